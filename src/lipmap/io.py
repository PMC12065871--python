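"""Readers and writers for peptide quantification reports, FASTA sequence
sets and per-residue fingerprint tables.

The universal exchange object is the *peptide quantification table*: a long
pandas DataFrame with one row per (sample, protein, peptide, assay channel)
carrying a linear-scale intensity.  ``LIP`` rows come from the limited
proteolysis (proteinase K + trypsin) channel; ``TC`` rows from the
trypsin-only control digested under denaturing conditions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: canonical column order of a peptide quantification table
QUANT_COLUMNS = [
    "sample_id",
    "condition",
    "replicate",
    "protein_id",
    "peptide_sequence",
    "assay_type",
    "intensity",
]

ASSAY_TYPES = ("LIP", "TC")

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")
_MOD_RE = re.compile(r"\[[^\]]*\]|\([^)]*\)")


class FormatError(ValueError):
    """Input file does not conform to the expected format."""


class IntegrityError(ValueError):
    """Input violates a table invariant (duplicate keys, bad values)."""


def strip_modifications(sequence: str) -> str:
    """Remove bracketed/parenthesised modification annotations.

    Search-engine exports annotate modified residues as e.g.
    ``VFM(Oxidation)K`` or ``C[Carbamidomethyl]``; mapping onto the protein
    sequence needs the plain residue string.
    """
    return _MOD_RE.sub("", sequence).upper().strip("_.")


def validate_quant_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the invariants of a peptide quantification table.

    Raises :class:`IntegrityError` / :class:`FormatError` on violation and
    returns the table (column-ordered) otherwise.
    """
    missing = [c for c in QUANT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    bad_assay = set(table["assay_type"].unique()) - set(ASSAY_TYPES)
    if bad_assay:
        raise FormatError(f"unknown assay_type value(s): {sorted(bad_assay)}")

    key = ["sample_id", "protein_id", "peptide_sequence", "assay_type"]
    dup = table.duplicated(subset=key, keep=False)
    if dup.any():
        first = table.loc[dup, key].iloc[0].tolist()
        raise IntegrityError(
            f"duplicate (sample, protein, peptide, assay) key; first offender: {first}"
        )

    for seq in table["peptide_sequence"].unique():
        if len(seq) < 1 or not set(seq) <= _AA20:
            raise IntegrityError(f"invalid peptide sequence: {seq!r}")

    # every sample maps to exactly one (condition, replicate)
    pairs = table.groupby("sample_id")[["condition", "replicate"]].nunique()
    bad = pairs[(pairs > 1).any(axis=1)]
    if len(bad):
        raise IntegrityError(
            f"sample(s) mapped to multiple (condition, replicate) pairs: "
            f"{list(bad.index)}"
        )

    if (table["intensity"].dropna() < 0).any():
        raise IntegrityError("negative intensity encountered")

    return table[QUANT_COLUMNS].reset_index(drop=True)


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") else ","


def read_peptide_report(
    path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a long-format peptide quantification report (TSV or CSV).

    Parameters
    ----------
    path:
        Delimited text file with a header.  The delimiter (tab or comma) is
        auto-detected from the header line.
    column_map:
        Optional mapping from canonical field name (``sample_id`` ...) to the
        column name used in the file.

    Rows whose intensity does not parse as a number (or is empty/zero) are
    dropped with a logged count: zero intensity means "not quantified" in
    DIA exports, never a true zero on the log scale.
    """
    with open(path, "r", newline="") as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty file")
        delim = _sniff_delimiter(header)
        fh.seek(0)
        raw = pd.read_csv(fh, sep=delim, dtype=str, keep_default_na=False)

    column_map = column_map or {}
    rename = {v: k for k, v in column_map.items()}
    raw = raw.rename(columns=rename)

    missing = [c for c in QUANT_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )

    intensity = pd.to_numeric(raw["intensity"], errors="coerce")
    keep = intensity.notna() & (intensity > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d row(s) with non-parsable or zero intensity",
            path,
            n_dropped,
        )

    table = raw.loc[keep, :].copy()
    table["intensity"] = intensity[keep]
    table["replicate"] = pd.to_numeric(table["replicate"]).astype(int)
    table["peptide_sequence"] = table["peptide_sequence"].map(strip_modifications)
    return validate_quant_table(table)


def write_peptide_report(table: pd.DataFrame, path) -> None:
    """Write a peptide quantification table as TSV (inverse of the reader)."""
    validate_quant_table(table).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# experiment design


@dataclass(frozen=True)
class ExperimentDesign:
    """Two-condition contrast layout: which condition is compared to which.

    ``contrast`` is an ordered (treatment, reference) pair; log2 fold changes
    downstream are treatment minus reference.
    """

    conditions: tuple[str, ...]
    contrast: tuple[str, str]
    replicates: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        treat, ref = self.contrast
        if treat == ref:
            raise ValueError("contrast members must be distinct")
        for c in self.contrast:
            if c not in self.conditions:
                raise ValueError(f"contrast condition {c!r} not in conditions")
        for c in self.contrast:
            n = self.replicates.get(c)
            if n is not None and n < 2:
                raise ValueError(
                    f"condition {c!r} needs >= 2 replicates, got {n}"
                )

    @classmethod
    def from_table(cls, table: pd.DataFrame, contrast: tuple[str, str]):
        """Derive the design from a quantification table's sample annotation."""
        anno = table[["sample_id", "condition", "replicate"]].drop_duplicates()
        reps = anno.groupby("condition")["replicate"].nunique().to_dict()
        return cls(
            conditions=tuple(sorted(anno["condition"].unique())),
            contrast=contrast,
            replicates=reps,
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read protein sequences; id is the header token before the first space.

    Sequences are upper-cased.  Duplicate ids raise :class:`IntegrityError`;
    an empty file raises :class:`FormatError`.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise IntegrityError(f"duplicate FASTA id: {record.id}")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for {record.id}")
        sequences[record.id] = seq
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return sequences


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# fingerprint table round-trip (definition of ResidueFingerprint lives in
# lipmap.fingerprint; (de)serialisation here with the other format code)

FINGERPRINT_COLUMNS = [
    "protein_id",
    "position",
    "residue",
    "score",
    "n_peptides",
    "detected",
    "significant",
]


def write_fingerprint_table(fingerprint, path) -> None:
    """Write one row per residue, positions 1..length ascending, as TSV.

    Undetected residues carry an empty score field — "not detected" is a
    distinct state from a zero score.
    """
    rows = []
    for i in range(fingerprint.length):
        detected = bool(fingerprint.detected[i])
        score = (
            f"{fingerprint.scores[i]:.6f}" if detected else ""
        )
        rows.append(
            {
                "protein_id": fingerprint.protein_id,
                "position": i + 1,
                "residue": fingerprint.sequence[i] if fingerprint.sequence else "X",
                "score": score,
                "n_peptides": int(fingerprint.n_peptides[i]),
                "detected": str(detected).lower(),
                "significant": str(bool(fingerprint.significant[i])).lower(),
            }
        )
    pd.DataFrame(rows, columns=FINGERPRINT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_fingerprint_table(path):
    """Read a fingerprint TSV written by :func:`write_fingerprint_table`."""
    from .fingerprint import ResidueFingerprint

    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"score": str, "detected": str, "significant": str},
        keep_default_na=False,
    )
    missing = [c for c in FINGERPRINT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {missing}")
    df = df.sort_values("position")
    n = len(df)
    scores = np.full(n, np.nan)
    has_score = df["score"].str.len() > 0
    scores[has_score.to_numpy()] = df.loc[has_score, "score"].astype(float)
    truthy = lambda col: df[col].str.lower().isin(["true", "1"]).to_numpy()
    return ResidueFingerprint(
        protein_id=str(df["protein_id"].iloc[0]),
        sequence="".join(df["residue"].astype(str)),
        scores=scores,
        n_peptides=df["n_peptides"].to_numpy(int),
        detected=truthy("detected"),
        significant=truthy("significant"),
    )
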