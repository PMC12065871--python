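"""Per-residue structural fingerprints.

Overlapping LiP peptides are located on their parent protein sequence and
their scores averaged per residue: the *amino-acid score* S_i of residue i
is the arithmetic mean of the scores of all quantified peptides covering i.
Residues covered by no quantified peptide are "not detected" (a state
distinct from a zero score); detected residues whose mean score exceeds the
threshold tau are called significant, and maximal runs of significant
residues are reported as regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import DEFAULT_TAU

logger = logging.getLogger(__name__)

__all__ = [
    "PeptidePlacement",
    "ResidueFingerprint",
    "locate_peptides",
    "aggregate_residue_scores",
    "call_regions",
    "species_specific_quantify",
    "DEFAULT_TAU",
]


@dataclass(frozen=True)
class PeptidePlacement:
    """Location of a peptide in its parent protein (1-based, inclusive)."""

    protein_id: str
    peptide_sequence: str
    start: int
    end: int
    ambiguous: bool = False

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.peptide_sequence):
            raise ValueError("placement span does not match peptide length")

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class ResidueFingerprint:
    """Per-residue score profile of one protein.

    ``scores[i]`` is NaN where ``detected[i]`` is False (residue covered by
    no quantified peptide); ``ambiguous[i]`` marks residues whose score
    includes a peptide that occurs more than once in the protein.
    """

    protein_id: str
    sequence: str
    scores: np.ndarray
    n_peptides: np.ndarray
    detected: np.ndarray
    significant: np.ndarray
    ambiguous: np.ndarray = field(default=None)  # type: ignore[assignment]
    tau: float = DEFAULT_TAU

    def __post_init__(self):
        if self.ambiguous is None:
            self.ambiguous = np.zeros(len(self.scores), bool)
        n = len(self.scores)
        for name in ("n_peptides", "detected", "significant", "ambiguous"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if np.any(self.significant & ~self.detected):
            raise ValueError("significant residue marked undetected")

    @property
    def length(self) -> int:
        return len(self.scores)

    def significant_positions(self) -> np.ndarray:
        """1-based positions called significant."""
        return np.nonzero(self.significant)[0] + 1


def locate_peptides(
    sequences: dict[str, str],
    peptides: list[tuple[str, str]],
) -> tuple[list[PeptidePlacement], list[tuple[str, str]]]:
    """Exact-substring placement of peptides on their claimed parent protein.

    Every occurrence is returned (overlaps allowed); peptides occurring more
    than once are flagged ambiguous on each placement.  Peptides that are not
    a substring of their parent go to the unmapped report instead.

    Returns ``(placements, unmapped)``.
    """
    placements: list[PeptidePlacement] = []
    unmapped: list[tuple[str, str]] = []
    for protein_id, peptide in peptides:
        if protein_id not in sequences:
            raise KeyError(f"protein {protein_id!r} not in sequence set")
        seq = sequences[protein_id]
        starts = []
        pos = seq.find(peptide)
        while pos != -1:
            starts.append(pos)
            pos = seq.find(peptide, pos + 1)  # overlapping occurrences count
        if not starts:
            unmapped.append((protein_id, peptide))
            continue
        ambiguous = len(starts) > 1
        for s in starts:
            placements.append(
                PeptidePlacement(
                    protein_id=protein_id,
                    peptide_sequence=peptide,
                    start=s + 1,
                    end=s + len(peptide),
                    ambiguous=ambiguous,
                )
            )
    if unmapped:
        logger.info("locate_peptides: %d peptide(s) unmapped", len(unmapped))
    return placements, unmapped


def aggregate_residue_scores(
    records: pd.DataFrame,
    placements: list[PeptidePlacement],
    protein_length: int,
    sequence: str = "",
    tau: float = DEFAULT_TAU,
    drop_ambiguous: bool = False,
) -> ResidueFingerprint:
    """Mean peptide score per residue for one protein.

    ``records`` is a differential-analysis table (LiP channel) for a single
    protein; ``placements`` its peptide placements.  Each placement of each
    quantified, tested peptide contributes its score to every residue it
    covers; S_i is the arithmetic mean of those contributions.  In strict
    mode (``drop_ambiguous``) multi-occurrence peptides are excluded;
    otherwise every occurrence contributes and covered residues are marked
    ambiguity-tainted.
    """
    pids = set(records["protein_id"].unique())
    if len(pids) > 1:
        raise ValueError(f"records span multiple proteins: {sorted(pids)}")
    score_by_peptide = dict(
        zip(records["peptide_sequence"], records["score"])
    )
    protein_id = next(iter(pids)) if pids else (
        placements[0].protein_id if placements else ""
    )

    total = np.zeros(protein_length)
    count = np.zeros(protein_length, int)
    tainted = np.zeros(protein_length, bool)
    for pl in placements:
        if pl.end > protein_length:
            raise ValueError(
                f"placement {pl.start}-{pl.end} exceeds protein length "
                f"{protein_length}"
            )
        score = score_by_peptide.get(pl.peptide_sequence)
        if score is None:  # peptide not quantified/tested in this contrast
            continue
        if pl.ambiguous and drop_ambiguous:
            continue
        sl = slice(pl.start - 1, pl.end)
        total[sl] += score
        count[sl] += 1
        if pl.ambiguous:
            tainted[sl] = True

    detected = count > 0
    scores = np.full(protein_length, np.nan)
    scores[detected] = total[detected] / count[detected]
    significant = detected & (np.nan_to_num(scores, nan=-1.0) > tau)
    return ResidueFingerprint(
        protein_id=protein_id,
        sequence=sequence,
        scores=scores,
        n_peptides=count,
        detected=detected,
        significant=significant,
        ambiguous=tainted,
        tau=tau,
    )


def call_regions(
    fingerprint: ResidueFingerprint,
) -> list[tuple[int, int, float]]:
    """Maximal contiguous runs of significant residues.

    Returns ``(start, end, mean_score)`` triples, 1-based inclusive; any
    non-significant or undetected residue breaks a run.
    """
    regions = []
    mask = fingerprint.significant
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            mean_score = float(np.mean(fingerprint.scores[i : j + 1]))
            regions.append((i + 1, j + 1, mean_score))
            i = j + 1
        else:
            i += 1
    return regions


def species_specific_quantify(
    table: pd.DataFrame,
    species_peptides: dict[str, set[str]],
) -> dict[str, tuple[float, float]]:
    """Relative proteoform levels from species-specific peptide intensities.

    For each species, the intensities (linear scale) of its specific
    peptides are averaged across samples and summed; fractions are taken
    over the total of all species.  Raises when a species has no quantified
    specific peptide.

    Returns ``{species: (summed_intensity, fraction)}``.
    """
    sums: dict[str, float] = {}
    for species, peptides in species_peptides.items():
        sub = table[table["peptide_sequence"].isin(peptides)]
        if sub.empty:
            raise ValueError(
                f"species {species!r}: no specific peptide quantified"
            )
        per_peptide = sub.groupby("peptide_sequence")["intensity"].mean()
        sums[species] = float(per_peptide.sum())
    total = sum(sums.values())
    return {sp: (s, s / total) for sp, s in sums.items()}
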