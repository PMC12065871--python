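"""Seeded generators of synthetic LiP-MS experiments with ground truth.

The generator emulates a two-condition LiP experiment on one protein:
an in-silico semi-specific tryptic digest produces overlapping peptides,
log-normal intensity noise is added on the log2 scale, and *accessibility
regions* — stretches whose protease accessibility differs between the
conditions — plant log2 fold changes on the LiP channel, attenuated by the
overlap fraction for peptides that straddle a region boundary.  Planted
covalent-modification sites depress every peptide containing them in both
the LiP and the trypsin-only control channel, which is what distinguishes
them from conformational effects downstream.

The default protein is the 140-residue human α-synuclein sequence with an
accessibility region at the NAC amyloid core (residues 61-95, log2 effect
2.0), the canonical monomer-vs-fibril comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .structmap import StructureModel

__all__ = [
    "ALPHA_SYNUCLEIN",
    "DigestionRules",
    "StructuralGroundTruth",
    "default_truth",
    "digest_in_silico",
    "simulate_lip_experiment",
    "simulate_dose_series",
    "make_toy_structure",
    "random_protein_sequence",
]

#: human α-synuclein (UniProt P37840), 140 residues; NAC = residues 61-95
ALPHA_SYNUCLEIN = (
    "MDVFMKGLSKAKEGVVAAAEKTKQGVAEAAGKTKEGVLYVGSKTKEGVVHGVATVAEKTK"
    "EQVTNVGGAVVTGVTAVAQKTVEGAGSIAAATGFVKKDQLGKNEEGAPQEGILEDMPVDP"
    "DNEAYEMPSEEGYQDYEPEA"
)


def random_protein_sequence(length: int, seed: int = 0, kr_period: int = 9) -> str:
    """Random test sequence with a tryptic site roughly every ``kr_period``
    residues so the in-silico digest yields overlapping peptides."""
    rng = np.random.default_rng(seed)
    pool = list("ACDEFGHILMNQSTVWY")  # no K/R/P: placed explicitly
    seq = [pool[rng.integers(len(pool))] for _ in range(length)]
    for i in range(kr_period - 1, length - 1, kr_period):
        seq[i] = "K" if rng.random() < 0.8 else "R"
    return "".join(seq)


#: fixed treatment-insensitive carrier sequences: the background proteome a
#: LiP run is measured against (protease autolysis products and co-measured
#: proteins); they supply the unchanged peptide majority that median
#: normalization and proteome-wide BH adjustment presuppose
CARRIER_SEQUENCES: tuple[tuple[str, str], ...] = tuple(
    (f"CARRIER_{i+1}", random_protein_sequence(length, seed=1000 + 97 * i))
    for i, length in enumerate((220, 230, 250, 210, 260, 240, 225, 245))
)


@dataclass(frozen=True)
class DigestionRules:
    """Semi-specific Trypsin/P digest parameters.

    Trypsin cuts after K/R but not before P; peptides of 6-40 residues with
    up to 2 missed cleavages are kept.  Half-tryptic peptides (one tryptic
    terminus, one nonspecific proteinase-K terminus) are sampled: a candidate
    whose nonspecific cut falls inside an accessibility region is kept with
    probability ``half_tryptic_fraction``, elsewhere with
    ``background_rate`` — proteinase K nicks a disordered chain everywhere,
    preferentially where accessibility differs.
    """

    cut_residues: str = "KR"
    no_cut_before: str = "P"
    min_length: int = 6
    max_length: int = 40
    max_missed_cleavages: int = 2
    half_tryptic_fraction: float = 0.30
    background_rate: float = 0.15
    #: per-missed-cleavage acceptance multiplier for sampled half-tryptic
    #: peptides; the default 0 means a proteinase-K fragment is bounded by
    #: the *nearest* tryptic cuts (missed-cleavage semi-tryptic forms are
    #: minor species in real digests and are left to the fully-tryptic
    #: enumeration)
    missed_cleavage_penalty: float = 0.0

    def __post_init__(self):
        if self.min_length < 6:
            raise ValueError("min_length must be >= 6")
        if self.max_length < self.min_length:
            raise ValueError("max_length must be >= min_length")
        for p in (self.half_tryptic_fraction, self.background_rate,
                  self.missed_cleavage_penalty):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class StructuralGroundTruth:
    """Planted truth of a synthetic LiP experiment.

    ``accessibility_regions`` are (start, end, log2 effect) triples (1-based,
    inclusive) applied to the LiP channel; ``covalent_sites`` are (position,
    log2 effect) pairs applied to both channels for peptides containing the
    position.  ``noise_cv`` is the typical fractional coefficient of
    variation of linear intensities (typical noise sd on the log2 scale =
    log2(1 + cv); 0 for noiseless checks).  Peptide noise is heteroscedastic
    as in real MS data: each peptide's variance is drawn from the scaled
    inverse-chi-square prior  s0^2 * d0 / chi^2_{d0}  with
    ``noise_prior_df`` = d0 and s0 = log2(1 + cv) — the hierarchical model
    the moderated t-test assumes (``noise_prior_df = inf`` gives a common
    variance for every peptide).
    """

    protein_id: str = "SYUA_SYNTH"
    sequence: str = ALPHA_SYNUCLEIN
    accessibility_regions: tuple[tuple[int, int, float], ...] = ((61, 95, 2.0),)
    covalent_sites: tuple[tuple[int, float], ...] = ()
    noise_cv: float = 0.10
    noise_prior_df: float = 4.0
    replicates: int = 4
    base_abundance_mean: float = 20.0
    base_abundance_sd: float = 1.5
    #: treatment-insensitive carrier proteins co-measured with the target
    #: (purified-protein LiP runs always contain protease autolysis products
    #: and other background peptides; they anchor median normalization)
    background_proteins: tuple[tuple[str, str], ...] = CARRIER_SEQUENCES
    seed: int = 0

    def __post_init__(self):
        n = len(self.sequence)
        for start, end, eff in self.accessibility_regions:
            if not (1 <= start <= end <= n):
                raise ValueError(f"region ({start},{end}) outside 1..{n}")
            if not math.isfinite(eff):
                raise ValueError("region effect must be finite")
        for pos, eff in self.covalent_sites:
            if not (1 <= pos <= n):
                raise ValueError(f"covalent site {pos} outside 1..{n}")
            if not math.isfinite(eff):
                raise ValueError("covalent effect must be finite")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not self.noise_prior_df > 0:
            raise ValueError("noise_prior_df must be > 0 (inf allowed)")
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate per condition")


def default_truth(seed: int = 0, **overrides) -> StructuralGroundTruth:
    """The default study conditions: α-synuclein, NAC region 61-95 at log2
    effect 2.0, CV 10%, 4 vs 4 replicates."""
    return replace(StructuralGroundTruth(seed=seed), **overrides)


# ---------------------------------------------------------------------------
# in-silico digestion


def _cleavage_sites(sequence: str, rules: DigestionRules) -> list[int]:
    """Positions i such that trypsin cuts between residues i and i+1
    (1-based; i.e. after residue i)."""
    sites = []
    for i in range(1, len(sequence)):
        if sequence[i - 1] in rules.cut_residues and sequence[i] not in rules.no_cut_before:
            sites.append(i)
    return sites


def digest_in_silico(
    sequence: str,
    rules: DigestionRules = DigestionRules(),
    seed: int = 0,
    accessible_regions: tuple[tuple[int, int], ...] = (),
) -> pd.DataFrame:
    """Enumerate fully-tryptic peptides and sample half-tryptic ones.

    Returns a DataFrame with columns ``peptide_sequence``, ``start``,
    ``end`` (1-based inclusive) and ``fully_tryptic``.  Fully-tryptic
    peptides are the complete set allowed by ``rules``; half-tryptic
    candidates keep one tryptic terminus while the other terminus is a
    nonspecific cut, accepted with the region-dependent probabilities of
    ``rules``.  Deterministic given (sequence, rules, seed).
    """
    n = len(sequence)
    if n < rules.min_length:
        return pd.DataFrame(
            columns=["peptide_sequence", "start", "end", "fully_tryptic"]
        )

    sites = _cleavage_sites(sequence, rules)
    boundaries = [0] + sites + [n]  # peptide spans boundaries[i]+1 .. boundaries[j]

    rows: list[tuple[str, int, int, bool]] = []
    seen: set[tuple[int, int]] = set()
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + 2 + rules.max_missed_cleavages, len(boundaries))):
            start, end = boundaries[i] + 1, boundaries[j]
            length = end - start + 1
            if rules.min_length <= length <= rules.max_length:
                rows.append((sequence[start - 1 : end], start, end, True))
                seen.add((start, end))

    tryptic_starts = [b + 1 for b in boundaries[:-1]]
    tryptic_ends = boundaries[1:]
    site_arr = np.array(sites, int)

    def in_region(cut_pos: int) -> bool:
        return any(s <= cut_pos <= e for s, e in accessible_regions)

    def n_missed(start: int, end: int) -> int:
        # tryptic sites strictly inside the peptide
        return int(np.sum((site_arr >= start) & (site_arr < end))) if len(site_arr) else 0

    rng = np.random.default_rng(seed)
    # tryptic N-terminus, nonspecific C-terminus (cut after `end`)
    for start in tryptic_starts:
        for end in range(start + rules.min_length - 1,
                         min(start + rules.max_length - 1, n - 1) + 1):
            mc = n_missed(start, end)
            if (start, end) in seen or mc > rules.max_missed_cleavages:
                continue
            p = rules.half_tryptic_fraction if in_region(end) else rules.background_rate
            if rng.random() < p * rules.missed_cleavage_penalty**mc:
                rows.append((sequence[start - 1 : end], start, end, False))
                seen.add((start, end))
    # nonspecific N-terminus (cut before `start`), tryptic C-terminus
    for end in tryptic_ends:
        for start in range(max(end - rules.max_length + 1, 2),
                           end - rules.min_length + 2):
            mc = n_missed(start, end)
            if (start, end) in seen or mc > rules.max_missed_cleavages:
                continue
            p = rules.half_tryptic_fraction if in_region(start - 1) else rules.background_rate
            if rng.random() < p * rules.missed_cleavage_penalty**mc:
                rows.append((sequence[start - 1 : end], start, end, False))
                seen.add((start, end))

    return pd.DataFrame(
        rows, columns=["peptide_sequence", "start", "end", "fully_tryptic"]
    )


# ---------------------------------------------------------------------------
# experiment simulation


def _planted_lip_effect(
    start: int, end: int, regions: tuple[tuple[int, int, float], ...]
) -> float:
    """Region effect attenuated by the covered fraction of the peptide."""
    length = end - start + 1
    total = 0.0
    for r_start, r_end, eff in regions:
        overlap = min(end, r_end) - max(start, r_start) + 1
        if overlap > 0:
            total += eff * overlap / length
    return total


def _contains_covalent(
    start: int, end: int, sites: tuple[tuple[int, float], ...]
) -> float:
    return sum(eff for pos, eff in sites if start <= pos <= end)


TREATMENT, REFERENCE = "treated", "control"


def simulate_lip_experiment(
    truth: StructuralGroundTruth,
    rules: DigestionRules = DigestionRules(),
    effect_scale: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate matched LiP and trypsin-only control quantification tables.

    Per peptide and sample, log2 intensity = base abundance + condition
    effect + N(0, log2(1+cv)) noise; intensities are exported on the linear
    scale.  The LiP channel receives overlap-weighted accessibility-region
    effects (scaled by ``effect_scale``) plus covalent-site effects; the
    control channel (fully-tryptic peptides only) receives covalent-site
    effects only.  Treatment-insensitive carrier proteins (see
    ``StructuralGroundTruth.background_proteins``) are co-simulated in both
    channels and anchor downstream median normalization, as protease-derived
    background peptides do in a real purified-protein run.  Returns
    ``(lip, tc, truth_record)``; ``truth_record['peptides']`` maps each
    protein's peptides to their planted per-channel effects.
    """
    regions = tuple(
        (s, e, eff * effect_scale) for s, e, eff in truth.accessibility_regions
    )
    sd = math.log2(1.0 + truth.noise_cv)
    samples = [
        (f"{cond}_{r}", cond, r)
        for cond in (TREATMENT, REFERENCE)
        for r in range(1, truth.replicates + 1)
    ]

    # the target protein carries the planted effects; carrier proteins are
    # treatment-insensitive and anchor downstream median normalization
    proteins = [
        (truth.protein_id, truth.sequence, regions, truth.covalent_sites)
    ] + [(pid, seq, (), ()) for pid, seq in truth.background_proteins]

    lip_rows, tc_rows = [], []
    truth_record = {
        "protein_id": truth.protein_id,
        "regions": [list(r) for r in regions],
        "covalent_sites": [list(s) for s in truth.covalent_sites],
        "noise_cv": truth.noise_cv,
        "replicates": truth.replicates,
        "seed": truth.seed,
        "peptides": {},
    }
    for p_idx, (pid, seq, p_regions, p_sites) in enumerate(proteins):
        peptides = digest_in_silico(
            seq,
            rules,
            seed=truth.seed + 7919 * p_idx,
            accessible_regions=tuple((s, e) for s, e, _ in p_regions),
        )
        if pid == truth.protein_id and peptides.empty:
            raise ValueError("digest of the target protein produced no peptides")
        rng = np.random.default_rng(truth.seed + 7919 * p_idx + 1)
        base = rng.normal(
            truth.base_abundance_mean, truth.base_abundance_sd, len(peptides)
        )
        if math.isinf(truth.noise_prior_df):
            pep_sd = np.full(len(peptides), sd)
        else:
            d0 = truth.noise_prior_df
            pep_sd = sd * np.sqrt(d0 / rng.chisquare(d0, len(peptides)))
        pep_record = truth_record["peptides"].setdefault(pid, {})
        for k, row in enumerate(peptides.itertuples(index=False)):
            lip_eff = _planted_lip_effect(row.start, row.end, p_regions)
            cov_eff = _contains_covalent(row.start, row.end, p_sites)
            pep_record[row.peptide_sequence] = {
                "start": int(row.start),
                "end": int(row.end),
                "fully_tryptic": bool(row.fully_tryptic),
                "base_abundance": float(base[k]),
                "lip_effect": lip_eff + cov_eff,
                "tc_effect": cov_eff if row.fully_tryptic else None,
            }
            for sample_id, cond, rep in samples:
                treat = cond == TREATMENT
                x = base[k] + (lip_eff + cov_eff if treat else 0.0)
                if sd > 0:
                    x += rng.normal(0.0, pep_sd[k])
                lip_rows.append(
                    (sample_id, cond, rep, pid, row.peptide_sequence, "LIP", 2.0**x)
                )
                if row.fully_tryptic:
                    x_tc = base[k] + (cov_eff if treat else 0.0)
                    if sd > 0:
                        x_tc += rng.normal(0.0, pep_sd[k])
                    tc_rows.append(
                        (sample_id, cond, rep, pid, row.peptide_sequence, "TC",
                         2.0**x_tc)
                    )

    cols = [
        "sample_id", "condition", "replicate", "protein_id",
        "peptide_sequence", "assay_type", "intensity",
    ]
    lip = pd.DataFrame(lip_rows, columns=cols)
    tc = pd.DataFrame(tc_rows, columns=cols)
    return lip, tc, truth_record


def simulate_dose_series(
    truth: StructuralGroundTruth,
    doses: np.ndarray,
    ec50: float,
    hill: float = 1.0,
    rules: DigestionRules = DigestionRules(),
) -> list[tuple[float, pd.DataFrame, pd.DataFrame]]:
    """Simulate one two-condition experiment per compound dose.

    The planted region effects are scaled by the log-logistic occupancy
    dose^h / (ec50^h + dose^h), so dose 0 plants nothing and a saturating
    dose reproduces :func:`simulate_lip_experiment`.  Returns a list of
    ``(dose, lip, tc)`` triples, all deterministic given ``truth.seed``.
    """
    doses = np.asarray(doses, float)
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")
    if ec50 <= 0:
        raise ValueError("ec50 must be > 0")
    out = []
    for dose in doses:
        occupancy = 0.0 if dose == 0 else dose**hill / (ec50**hill + dose**hill)
        lip, tc, _ = simulate_lip_experiment(truth, rules, effect_scale=occupancy)
        out.append((float(dose), lip, tc))
    return out


# ---------------------------------------------------------------------------
# toy structures and sequences


def make_toy_structure(
    length: int, pocket: set[int], seed: int = 0
) -> StructureModel:
    """Idealized α-helix test structure (Cα + one pseudo side-chain atom).

    Backbone geometry: 1.5 Å rise and 100° twist per residue at 2.3 Å
    radius, giving consecutive Cα-Cα distances near 3.8 Å; the pseudo
    side-chain atom sits 1 Å further out.  A small seeded jitter (0.05 Å)
    decorrelates structures across seeds.
    """
    if length < 10:
        raise ValueError("length must be >= 10")
    pocket = set(pocket)
    if pocket and not pocket <= set(range(1, length + 1)):
        raise ValueError("pocket residues outside 1..length")
    rng = np.random.default_rng(seed)
    atoms: dict[int, np.ndarray] = {}
    names: dict[int, list[str]] = {}
    elements: dict[int, list[str]] = {}
    residue_names: dict[int, str] = {}
    for i in range(1, length + 1):
        theta = math.radians(100.0 * (i - 1))
        z = 1.5 * (i - 1)
        ca = np.array([2.3 * math.cos(theta), 2.3 * math.sin(theta), z])
        cb = np.array([3.3 * math.cos(theta), 3.3 * math.sin(theta), z])
        jitter = rng.normal(0.0, 0.05, (2, 3))
        atoms[i] = np.vstack([ca, cb]) + jitter
        names[i] = ["CA", "CB"]
        elements[i] = ["C", "C"]
        residue_names[i] = "ALA"
    return StructureModel(
        chain_id="A",
        atoms=atoms,
        residue_names=residue_names,
        atom_names=names,
        elements=elements,
        pocket=pocket,
    )
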