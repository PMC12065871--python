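"""End-to-end convenience pipeline: quantification tables to fingerprints."""

from __future__ import annotations

import pandas as pd

from .io import ExperimentDesign
from .fingerprint import (
    ResidueFingerprint,
    aggregate_residue_scores,
    locate_peptides,
)
from .stats import (
    DEFAULT_TAU,
    differential_analysis,
    log2_and_median_normalize,
    tryptic_control_normalize,
)

__all__ = ["run_fingerprint_pipeline"]


def run_fingerprint_pipeline(
    lip: pd.DataFrame,
    sequences: dict[str, str],
    contrast: tuple[str, str],
    tc: pd.DataFrame | None = None,
    tau: float = DEFAULT_TAU,
    mod="auto",
) -> tuple[dict[str, ResidueFingerprint], pd.DataFrame]:
    """Normalize, test and aggregate: one fingerprint per protein.

    ``lip`` (and optionally ``tc``, applied as tryptic-control
    normalization) are linear-scale quantification tables.  Returns
    ``({protein_id: fingerprint}, differential_records)``.
    """
    lip_log = log2_and_median_normalize(lip)
    if tc is not None:
        tc_log = log2_and_median_normalize(tc)
        lip_log = tryptic_control_normalize(lip_log, tc_log)
    design = ExperimentDesign.from_table(lip_log, contrast)
    records = differential_analysis(lip_log, design, assay="LIP", mod=mod)

    fingerprints: dict[str, ResidueFingerprint] = {}
    for protein_id, rec in records.groupby("protein_id"):
        seq = sequences[protein_id]
        placements, _ = locate_peptides(
            {protein_id: seq},
            [(protein_id, p) for p in rec["peptide_sequence"].unique()],
        )
        fingerprints[protein_id] = aggregate_residue_scores(
            rec, placements, len(seq), sequence=seq, tau=tau
        )
    return fingerprints, records
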