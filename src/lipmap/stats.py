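"""Differential peptide statistics for LiP-MS.

The analysis chain is: log2 transform + median normalization, optional
tryptic-control normalization (removes covalent-modification and abundance
effects from the LiP channel), per-peptide moderated t-test with
empirical-Bayes variance shrinkage, Benjamini-Hochberg adjustment across all
tested peptides, and the peptide score

    s = -log10(q) * |log2FC|

which combines significance and effect size into a single non-negative
number.  The same machinery applied to the trypsin-only control channel
flags candidate covalent-modification peptides (intensity decreases in the
control digest indicate a mass-shifted, i.e. modified, peptide population).
Fisher-exact hit-list enrichment and ThT aggregation-kinetics fitting round
out the module.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps

from .io import ExperimentDesign, validate_quant_table

logger = logging.getLogger(__name__)

__all__ = [
    "ModerationParams",
    "log2_and_median_normalize",
    "tryptic_control_normalize",
    "moderated_ttest",
    "estimate_moderation",
    "adjust_bh",
    "peptide_score",
    "differential_analysis",
    "detect_covalent_candidates",
    "fisher_enrichment",
    "ThTCurveFit",
    "fit_tht_curve",
]


# ---------------------------------------------------------------------------
# normalization


def log2_and_median_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Log2-transform linear intensities and equalize per-sample medians.

    Each sample is shifted by a constant so that its median log2 intensity
    equals the median of all per-sample medians.  Returns a new table whose
    ``intensity`` column is on the log2 scale.
    """
    table = validate_quant_table(table)
    out = table.copy()
    with np.errstate(divide="ignore"):
        out["intensity"] = np.log2(out["intensity"].to_numpy(float))
    out.loc[~np.isfinite(out["intensity"]), "intensity"] = np.nan

    medians = out.groupby("sample_id")["intensity"].median()
    empty = medians[medians.isna()]
    if len(empty):
        raise ValueError(
            f"sample(s) with zero quantified peptides: {list(empty.index)}"
        )
    target = float(np.median(medians.to_numpy()))
    shift = out["sample_id"].map(target - medians)
    out["intensity"] = out["intensity"] + shift
    return out


def tryptic_control_normalize(
    lip: pd.DataFrame, tc: pd.DataFrame
) -> pd.DataFrame:
    """Remove the trypsin-control-explained component from LiP intensities.

    For every (protein, peptide, sample) present in both channels:

        adjusted = lip - tc + median_over_samples(tc for that peptide)

    so that abundance or covalent-modification effects (which show in the
    control channel) cancel, while purely conformational effects (LiP channel
    only) survive unchanged.  Both inputs must already be on the log2 scale.
    LiP rows without a same-sample control partner are dropped with a logged
    count.
    """
    key = ["protein_id", "peptide_sequence", "sample_id"]
    tc_int = tc.set_index(key)["intensity"]
    tc_median = tc.groupby(["protein_id", "peptide_sequence"])["intensity"].median()

    merged = lip.merge(
        tc_int.rename("tc_intensity"),
        left_on=key,
        right_index=True,
        how="left",
    )
    has_partner = merged["tc_intensity"].notna()
    n_dropped = int((~has_partner).sum())
    if n_dropped:
        logger.info(
            "tryptic_control_normalize: dropped %d LiP row(s) without a "
            "same-sample control partner",
            n_dropped,
        )
    out = merged.loc[has_partner].copy()
    med = pd.MultiIndex.from_frame(out[["protein_id", "peptide_sequence"]])
    out["intensity"] = (
        out["intensity"].to_numpy()
        - out["tc_intensity"].to_numpy()
        + tc_median.reindex(med).to_numpy()
    )
    return out.drop(columns="tc_intensity").reset_index(drop=True)


# ---------------------------------------------------------------------------
# moderated t-test


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes variance-shrinkage hyperparameters.

    ``prior_df`` (d0) is the weight of the prior variance ``prior_var``
    (s0^2, in squared log2-intensity units) relative to the per-peptide
    residual degrees of freedom.  d0 = 0 recovers the ordinary pooled
    t-test; d0 = inf fixes every peptide's variance at s0^2.
    """

    prior_df: float
    prior_var: float

    def __post_init__(self):
        if self.prior_df < 0:
            raise ValueError("prior_df must be >= 0")
        if self.prior_df > 0 and not self.prior_var > 0:
            raise ValueError("prior_var must be > 0 when prior_df > 0")


#: no shrinkage: ordinary pooled two-sample t-test
NO_MODERATION = ModerationParams(prior_df=0.0, prior_var=1.0)


def moderated_ttest(
    treatment: np.ndarray,
    reference: np.ndarray,
    mod: ModerationParams = NO_MODERATION,
) -> tuple[float, float, float, float]:
    """Two-sided moderated t-test on two vectors of log2 intensities.

    Pools an equal-variance estimate s^2 with ``d = nT + nR - 2`` residual
    degrees of freedom, shrinks it toward the prior,

        s_post^2 = (d0*s0^2 + d*s^2) / (d0 + d),

    and refers  t = log2FC / (s_post * sqrt(1/nT + 1/nR))  to a
    t-distribution with d + d0 degrees of freedom (standard normal when d0
    is infinite).

    Returns ``(log2FC, t, df_total, p_value)``.
    """
    x = np.asarray(treatment, float)
    y = np.asarray(reference, float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    nt, nr = len(x), len(y)
    if nt < 2 or nr < 2:
        raise ValueError("insufficient replicates: need >= 2 values per side")

    log2fc = float(x.mean() - y.mean())
    d = nt + nr - 2
    s2 = (np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2)) / d

    d0, s02 = mod.prior_df, mod.prior_var
    if math.isinf(d0):
        s2_post = s02
        df_total = math.inf
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d + d0

    se = math.sqrt(s2_post * (1.0 / nt + 1.0 / nr))
    if se == 0:
        t = 0.0 if log2fc == 0 else math.copysign(math.inf, log2fc)
    else:
        t = log2fc / se
    if math.isinf(df_total):
        p = 2.0 * sps.norm.sf(abs(t))
    else:
        p = 2.0 * sps.t.sf(abs(t), df_total)
    return log2fc, float(t), float(df_total), float(min(p, 1.0))


def estimate_moderation(
    variances: np.ndarray, residual_df: int
) -> ModerationParams:
    """Moment-match a scaled inverse-chi-square prior to observed variances.

    Under the hierarchical model s^2 | sigma^2 ~ sigma^2 * chi^2_d / d with
    sigma^2 ~ s0^2 * d0 / chi^2_{d0}, the log sample variances follow a
    shifted log-F distribution whose first two moments involve digamma /
    trigamma functions; matching them yields closed-form (d0, s0^2)
    estimates.  A non-positive excess spread in log s^2 means the variances
    are consistent with a single common value and d0 = inf is returned.
    """
    s2 = np.asarray(variances, float)
    s2 = s2[np.isfinite(s2)]
    if len(s2) < 10:
        raise ValueError("need >= 10 finite variances")
    if np.all(s2 <= 0):
        raise ValueError("degenerate variance set: all variances zero")
    # zero sample variances arise from tied intensities; they carry no
    # information about the spread of true variances on the log scale
    s2 = s2[s2 > 0]
    d = float(residual_df)

    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + math.log(d / 2.0)
    e_bar = float(np.mean(e))
    n = len(e)
    excess = float(
        np.mean((e - e_bar) ** 2) * n / (n - 1) - special.polygamma(1, d / 2.0)
    )
    if excess <= 0:
        return ModerationParams(prior_df=math.inf, prior_var=float(np.exp(e_bar)))

    # invert trigamma(d0/2) = excess by Newton iteration (monotone, convex)
    def _trigamma_inverse(x: float) -> float:
        if x > 1e7:
            return 1.0 / math.sqrt(x)
        if x < 1e-6:
            return 1.0 / x
        y = 0.5 + 1.0 / x
        for _ in range(50):
            tri = special.polygamma(1, y)
            dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
            y += dif
            if abs(dif) < 1e-10 * y:
                break
        return y

    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    if not math.isfinite(d0):
        return ModerationParams(prior_df=math.inf, prior_var=float(np.exp(e_bar)))
    s02 = float(np.exp(e_bar + special.digamma(half_d0) - math.log(half_d0)))
    return ModerationParams(prior_df=d0, prior_var=s02)


# ---------------------------------------------------------------------------
# multiple testing and scoring


def adjust_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( p_(j) * n / j ), capped at 1, returned in the
    input order.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def peptide_score(log2fc: float, q_value: float) -> float:
    """Combined effect/significance score  -log10(q) * |log2FC|  (>= 0)."""
    if not 0 < q_value <= 1:
        raise ValueError("q_value must lie in (0, 1]")
    return float(-math.log10(q_value) * abs(log2fc))


#: default residue/score significance threshold: -log10(0.05) * |log2(2)|
DEFAULT_TAU = -math.log10(0.05) * abs(math.log2(2.0))


# ---------------------------------------------------------------------------
# per-peptide differential analysis


def differential_analysis(
    table: pd.DataFrame,
    design: ExperimentDesign,
    assay: str = "LIP",
    mod: ModerationParams | str = "auto",
    min_reps: int = 2,
) -> pd.DataFrame:
    """Per-peptide differential abundance between the contrast conditions.

    ``table`` must be log2-normalized.  One output row per (protein, peptide)
    with at least ``min_reps`` quantified replicates on each side of the
    contrast; BH adjustment is applied once across all tested peptides of the
    requested assay channel, and the peptide score is attached.

    ``mod='auto'`` estimates the shrinkage hyperparameters from the pooled
    per-peptide variances (falling back to no shrinkage when fewer than 10
    peptides are testable).

    Returns a DataFrame with columns protein_id, peptide_sequence,
    assay_type, log2FC, t, p_value, q_value, score, n_treatment, n_reference.
    """
    treat, ref = design.contrast
    sub = table[table["assay_type"] == assay]
    present = set(sub["condition"].unique())
    for c in design.contrast:
        if c not in present:
            raise ValueError(f"contrast condition {c!r} absent from table")

    groups: list[tuple[str, str, np.ndarray, np.ndarray]] = []
    n_skipped = 0
    for (pid, pep), g in sub.groupby(["protein_id", "peptide_sequence"], sort=True):
        x = g.loc[g["condition"] == treat, "intensity"].dropna().to_numpy(float)
        y = g.loc[g["condition"] == ref, "intensity"].dropna().to_numpy(float)
        if len(x) < min_reps or len(y) < min_reps:
            n_skipped += 1
            continue
        groups.append((pid, pep, x, y))
    if n_skipped:
        logger.info(
            "differential_analysis(%s): skipped %d peptide(s) with "
            "insufficient replicates",
            assay,
            n_skipped,
        )
    if not groups:
        return pd.DataFrame(
            columns=[
                "protein_id", "peptide_sequence", "assay_type", "log2FC",
                "t", "p_value", "q_value", "score", "n_treatment",
                "n_reference",
            ]
        )

    if mod == "auto":
        dfs = [len(x) + len(y) - 2 for _, _, x, y in groups]
        variances = np.array(
            [
                (np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2)) / d
                for (_, _, x, y), d in zip(groups, dfs)
            ]
        )
        if len(variances) >= 10:
            # moment matching assumes one common residual df; the typical
            # (modal) df across peptides is used
            d_common = int(np.bincount(dfs).argmax())
            mod = estimate_moderation(variances, d_common)
        else:
            mod = NO_MODERATION
    assert isinstance(mod, ModerationParams)

    rows = []
    for pid, pep, x, y in groups:
        log2fc, t, df_total, p = moderated_ttest(x, y, mod)
        rows.append(
            {
                "protein_id": pid,
                "peptide_sequence": pep,
                "assay_type": assay,
                "log2FC": log2fc,
                "t": t,
                "p_value": max(p, 1e-300),
                "n_treatment": len(x),
                "n_reference": len(y),
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = adjust_bh(out["p_value"].to_numpy())
    out["score"] = [
        peptide_score(fc, q) for fc, q in zip(out["log2FC"], out["q_value"])
    ]
    return out[
        [
            "protein_id", "peptide_sequence", "assay_type", "log2FC", "t",
            "p_value", "q_value", "score", "n_treatment", "n_reference",
        ]
    ]


def detect_covalent_candidates(
    tc_records: pd.DataFrame, fc_cut: float = 1.0, q_cut: float = 0.05
) -> pd.DataFrame:
    """Flag trypsin-control peptides whose intensity drops under treatment.

    A significant *decrease* (log2FC <= -fc_cut, q <= q_cut) of a
    fully-tryptic control peptide indicates loss of the unmodified form,
    i.e. a candidate covalent-modification site; increases are not flagged.

    Returns the input records with a boolean ``covalent_candidate`` column
    plus per-protein ``flagged``/``detected`` counts in ``.attrs['summary']``
    (e.g. "3 of 6 flagged").
    """
    rec = tc_records.copy()
    rec["covalent_candidate"] = (rec["log2FC"] <= -fc_cut) & (
        rec["q_value"] <= q_cut
    )
    summary = (
        rec.groupby("protein_id")["covalent_candidate"]
        .agg(flagged="sum", detected="count")
        .astype(int)
        .reset_index()
    )
    summary["report"] = [
        f"{f} of {d} flagged" for f, d in zip(summary["flagged"], summary["detected"])
    ]
    rec.attrs["summary"] = summary
    return rec


# ---------------------------------------------------------------------------
# enrichment


def fisher_enrichment(
    hits: set[str],
    background: set[str],
    annotation: dict[str, set[str]],
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Fisher-exact enrichment of an annotation over a hit list.

    For each term, the 2x2 table (hit&term, hit&!term, !hit&term, !hit&!term)
    over the background universe is tested; BH adjustment is applied across
    terms.  The odds ratio reported is the sample odds ratio a*d / (b*c)
    (inf when b*c == 0 and a*d > 0).
    """
    if not hits or not background:
        raise ValueError("hits and background must be non-empty")
    hits = set(hits)
    background = set(background)
    if not hits <= background:
        raise ValueError("hits must be a subset of background")

    rows = []
    for term, members in annotation.items():
        members = set(members) & background
        a = len(hits & members)
        b = len(hits - members)
        c = len(members - hits)
        d = len(background) - a - b - c
        odds, p = sps.fisher_exact([[a, b], [c, d]], alternative=alternative)
        sample_or = (a * d) / (b * c) if b * c > 0 else (
            math.inf if a * d > 0 else 0.0
        )
        rows.append(
            {"term": term, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": sample_or, "p_value": max(float(p), 1e-300)}
        )
    out = pd.DataFrame(rows)
    out["q_value"] = adjust_bh(out["p_value"].to_numpy())
    return out.sort_values("p_value").reset_index(drop=True)


# ---------------------------------------------------------------------------
# ThT aggregation kinetics


@dataclass(frozen=True)
class ThTCurveFit:
    """Sigmoid fit of a Thioflavin-T aggregation time course.

    F(t) = F0 + (Fmax - F0) / (1 + exp(-k (t - t_half))); ``t_half`` is the
    aggregation half-time in hours, ``t_end`` the endpoint fluorescence
    (mean of the last three observed points).  Flat curves — no detectable
    aggregation — report ``t_half = inf``.
    """

    f0: float
    fmax: float
    k: float
    t_half: float
    t_end: float
    residual_rms: float
    flat: bool = False
    extrapolated: bool = False


def fit_tht_curve(times: np.ndarray, fluorescence: np.ndarray) -> ThTCurveFit:
    """Least-squares logistic fit of a ThT fluorescence time course.

    Requires >= 6 strictly increasing time points.  Curves whose fitted
    amplitude is below three times the residual RMS (or that fail to
    converge) are reported flat with an infinite half-time.
    """
    t = np.asarray(times, float)
    f = np.asarray(fluorescence, float)
    if len(t) < 6:
        raise ValueError("need >= 6 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    t_end = float(np.mean(f[-3:]))

    def logistic(tt, f0, fmax, k, th):
        return f0 + (fmax - f0) / (1.0 + np.exp(-k * (tt - th)))

    f0_guess, fmax_guess = float(f[0]), float(f.max())
    span = max(fmax_guess - f0_guess, 1e-12)
    # crude half-time guess: first crossing of the midpoint
    above = np.nonzero(f >= f0_guess + span / 2)[0]
    th_guess = float(t[above[0]]) if len(above) else float(t.mean())
    k_guess = 4.0 / max((t[-1] - t[0]) / 4.0, 1e-6)

    try:
        with warnings.catch_warnings():
            # flat curves legitimately yield unestimable covariance
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                logistic,
                t,
                f,
                p0=[f0_guess, fmax_guess, k_guess, th_guess],
                maxfev=20000,
            )
        f0, fmax, k, th = (float(v) for v in popt)
        resid = f - logistic(t, *popt)
        rms = float(np.sqrt(np.mean(resid**2)))
        converged = True
    except RuntimeError:
        f0, fmax, k, th = f0_guess, fmax_guess, 0.0, math.inf
        rms = float(np.std(f))
        converged = False

    amplitude = abs(fmax - f0)
    scale = max(abs(f0), abs(fmax), float(np.max(np.abs(f))), 1.0)
    if not converged or amplitude <= 3.0 * rms or amplitude < 1e-6 * scale:
        return ThTCurveFit(
            f0=min(f0, fmax), fmax=max(f0, fmax), k=0.0, t_half=math.inf,
            t_end=t_end, residual_rms=rms, flat=True,
        )
    if fmax < f0:  # decreasing logistic: reparameterize to Fmax >= F0
        f0, fmax, k = fmax, f0, -k
    extrapolated = not (t[0] <= th <= t[-1])
    return ThTCurveFit(
        f0=f0, fmax=fmax, k=k, t_half=th, t_end=t_end,
        residual_rms=rms, flat=False, extrapolated=extrapolated,
    )
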