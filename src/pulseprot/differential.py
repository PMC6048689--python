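"""Cue-induced differential nascent-proteome calling.

The pipeline mirrors the standard pSILAC workflow for one-sample designs:

1. log2-transform H/M ratios (stimulated vs control synthesis) and
   median-center each sample, after discarding quantifications with a
   ratio count below 2;
2. flag per protein and condition whether the change is *consistent*:
   quantified in more than 50% of biological replicates, replicate SD
   of at most 1, and absolute mean log2 ratio above 0.3;
3. test each protein's mean log2 ratio against zero with an
   empirical-Bayes moderated one-sample t-test: per-protein sample
   variances are shrunk toward a pooled prior variance ``s0^2`` with
   prior degrees of freedom ``d0`` estimated by moments from the
   log-variance distribution (scaled chi-square hierarchical model),
   giving ``s_tilde^2 = (d0*s0^2 + d*s^2) / (d0 + d)`` and a Student-t
   reference with ``d0 + d`` degrees of freedom;
4. control the false discovery rate with the Benjamini-Hochberg step-up
   adjustment.

Each (cue, modulator, pulse) condition is normalized and tested
separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import EstimationError, NormalizationError, ValidationError
from .experiment import QuantMatrix, SampleInfo

__all__ = [
    "FilterCriteria",
    "RatioMatrix",
    "VariancePrior",
    "normalize_log_ratios",
    "filter_consistent",
    "estimate_variance_prior",
    "moderated_test",
    "bh_adjust",
    "call_changes",
]

#: d0 values beyond this are reported as infinite (normal reference tails).
_D0_CAP = 1e6


@dataclass(frozen=True)
class FilterCriteria:
    """Replicate-consistency thresholds for a nascent-protein change.

    Defaults follow the standard criteria: quantified in strictly more
    than half of the biological replicates, replicate SD at most 1, and
    absolute average log2 ratio strictly above 0.3; quantifications need
    a minimum peptide ratio count of 2.
    """

    min_fraction_quantified: float = 0.5  # strict >
    max_replicate_sd: float = 1.0  # <=
    min_abs_avg_ratio: float = 0.3  # strict >
    min_ratio_count: int = 2


class RatioMatrix:
    """Normalized per-replicate log2(H/M) values grouped by condition.

    ``values`` is a proteins x samples DataFrame of median-centered log2
    ratios (NaN = not quantified); ``offsets`` records the per-sample
    median that was subtracted, for audit.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        samples: Sequence[SampleInfo],
        offsets: pd.Series,
    ):
        if list(values.columns) != [s.sample_id for s in samples]:
            raise ValidationError("values columns must match sample ids")
        self.values = values
        self.samples = list(samples)
        self.offsets = offsets

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    def conditions(self) -> list[tuple[str, str, int]]:
        seen: list[tuple[str, str, int]] = []
        for s in self.samples:
            if s.condition not in seen:
                seen.append(s.condition)
        return seen

    def condition_values(self, condition: tuple[str, str, int]) -> pd.DataFrame:
        """Replicate columns (proteins x replicates) of one condition."""
        sids = [s.sample_id for s in self.samples if s.condition == tuple(condition)]
        if not sids:
            raise KeyError(f"condition {condition} not in design")
        return self.values[sids]


def normalize_log_ratios(
    quant: QuantMatrix,
    samples: Sequence[SampleInfo] | None = None,
    min_ratio_count: int = 2,
) -> RatioMatrix:
    """Median-normalized log2(H/M) ratios.

    Ratios backed by fewer than ``min_ratio_count`` peptide ratio
    measurements are excluded before the log transform.  Each sample's
    median log2 ratio is subtracted, so the per-sample median of the
    output is 0; missing stays missing.

    Raises
    ------
    NormalizationError
        If a selected sample has no quantified ratio at all (its median,
        and hence the normalization offset, would be undefined).
    """
    if samples is None:
        samples = quant.samples
    sids = [s.sample_id for s in samples]
    ratio = quant.field("ratio_HM")[sids]
    count = quant.field("ratio_count_HM")[sids]
    ratio = ratio.where(count >= min_ratio_count)
    log2r = np.log2(ratio)
    offsets = log2r.median(axis=0, skipna=True)
    empty = offsets.index[offsets.isna()]
    if len(empty):
        raise NormalizationError(
            f"sample {empty[0]!r} has no quantified H/M ratio; cannot normalize"
        )
    return RatioMatrix(log2r.sub(offsets, axis=1), list(samples), offsets)


def _condition_summary(block: pd.DataFrame) -> pd.DataFrame:
    n_total = block.shape[1]
    n_quant = block.notna().sum(axis=1)
    return pd.DataFrame(
        {
            "n_total": n_total,
            "n_quantified": n_quant,
            "frac_quantified": n_quant / n_total,
            "mean": block.mean(axis=1),
            "sd": block.std(axis=1, ddof=1),
        }
    )


def filter_consistent(
    ratios: RatioMatrix,
    criteria: FilterCriteria | None = None,
    condition: tuple[str, str, int] | None = None,
) -> pd.DataFrame:
    """Consistency flags and replicate summaries for one condition.

    A protein is *consistent* iff quantified in strictly more than
    ``min_fraction_quantified`` of the condition's replicates, replicate
    SD (n-1 denominator over quantified replicates) at most
    ``max_replicate_sd``, and absolute mean strictly above
    ``min_abs_avg_ratio``.  Proteins quantified in fewer than 2
    replicates have undefined SD and are never consistent; they are
    flagged via ``sd_defined``.

    Returns a proteins-indexed DataFrame with columns ``n_total``,
    ``n_quantified``, ``frac_quantified``, ``mean``, ``sd``,
    ``sd_defined``, ``consistent``, ``direction`` ("up"/"down"/NA).
    """
    criteria = criteria or FilterCriteria()
    if condition is None:
        conds = ratios.conditions()
        if len(conds) != 1:
            raise ValidationError("condition must be given for a multi-condition matrix")
        condition = conds[0]
    block = ratios.condition_values(condition)
    out = _condition_summary(block)
    out["sd_defined"] = out["n_quantified"] >= 2
    out["consistent"] = (
        (out["frac_quantified"] > criteria.min_fraction_quantified)
        & out["sd_defined"]
        & (out["sd"] <= criteria.max_replicate_sd)
        & (out["mean"].abs() > criteria.min_abs_avg_ratio)
    )
    direction = pd.Series(pd.NA, index=out.index, dtype=object)
    direction[out["mean"] > 0] = "up"
    direction[out["mean"] < 0] = "down"
    out["direction"] = direction
    return out


# ---------------------------------------------------------------------------
# Empirical-Bayes variance shrinkage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariancePrior:
    """Scaled chi-square prior on per-protein variances.

    ``df_prior`` may be ``math.inf``, in which case every posterior
    variance equals ``var_prior`` and test statistics use normal tails.
    """

    df_prior: float
    var_prior: float


def _trigamma_inverse(y: float) -> float:
    """Solve psi'(x) = y for x > 0 (psi' is strictly decreasing)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    lo, hi = 1e-8, 1e8
    f = lambda x: special.polygamma(1, x) - y
    if f(hi) > 0:  # y below psi'(hi): x beyond cap, treat as huge
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))


def estimate_variance_prior(
    variances: np.ndarray | pd.Series,
    dfs: np.ndarray | pd.Series | float,
) -> VariancePrior:
    """Moment estimation of the variance prior (d0, s0^2).

    Under the hierarchical scaled chi-square model,
    ``e_g = log s_g^2 - psi(d_g/2) + log(d_g/2)`` has mean
    ``log s0^2 - psi(d0/2) + log(d0/2)`` and variance
    ``psi'(d_g/2) + psi'(d0/2)``.  The prior df solves
    ``psi'(d0/2) = var(e) - mean(psi'(d_g/2))`` by monotone trigamma
    inversion; ``s0^2`` then comes from the mean equation.  A non-positive
    variance excess means the observed variances are no more dispersed
    than sampling alone explains: the prior df is infinite and ``s0^2``
    is the bias-corrected geometric mean ``exp(mean(e))``.

    Requires at least 10 proteins with positive variance and at least
    one degree of freedom.
    """
    s2 = np.asarray(variances, dtype=float)
    d = np.broadcast_to(np.asarray(dfs, dtype=float), s2.shape).copy()
    ok = np.isfinite(s2) & (s2 > 0) & (d >= 1)
    s2, d = s2[ok], d[ok]
    if s2.size < 10:
        raise EstimationError(
            f"need >= 10 proteins with positive variance and df >= 1, got {s2.size}"
        )
    e = np.log(s2) - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - float(special.polygamma(1, d / 2.0).mean())
    if excess <= 0:
        return VariancePrior(math.inf, math.exp(emean))
    d0 = 2.0 * _trigamma_inverse(excess)
    if d0 > _D0_CAP:
        return VariancePrior(math.inf, math.exp(emean))
    s0_sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return VariancePrior(d0, s0_sq)


def moderated_test(
    ratios: RatioMatrix | pd.DataFrame,
    condition: tuple[str, str, int] | None = None,
    prior: VariancePrior | None = None,
) -> pd.DataFrame:
    """Moderated one-sample t-test of mean log2 ratio against zero.

    Parameters
    ----------
    ratios : RatioMatrix or DataFrame
        Either a full RatioMatrix (give ``condition``) or a plain
        proteins x replicates DataFrame of log2 ratios.
    prior : VariancePrior, optional
        Estimated from the data when omitted.  ``df_prior = 0`` gives the
        ordinary one-sample t; ``df_prior = inf`` uses the prior variance
        for every protein with normal reference tails.

    Returns
    -------
    DataFrame with per-protein ``n``, ``mean``, ``var``, ``df``,
    ``var_post``, ``t``, ``p``, ``df_total`` and a ``tested`` flag
    (proteins with fewer than 2 quantified replicates are reported
    untested, with NaN statistics, not dropped).
    """
    if isinstance(ratios, RatioMatrix):
        if condition is None:
            conds = ratios.conditions()
            if len(conds) != 1:
                raise ValidationError("condition must be given for a multi-condition matrix")
            condition = conds[0]
        block = ratios.condition_values(condition)
    else:
        block = ratios

    n = block.notna().sum(axis=1).astype(float)
    mean = block.mean(axis=1)
    var = block.var(axis=1, ddof=1)
    df = n - 1.0
    tested = n >= 2

    if prior is None:
        prior = estimate_variance_prior(var[tested], df[tested])
    d0, s0 = prior.df_prior, prior.var_prior

    if math.isinf(d0):
        var_post = pd.Series(s0, index=block.index).where(tested)
        df_total = pd.Series(math.inf, index=block.index).where(tested)
    else:
        var_post = ((d0 * s0 + df * var) / (d0 + df)).where(tested)
        df_total = (d0 + df).where(tested)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var_post / n)
    # all replicate values identical to 0 with a zero posterior variance:
    # define t = 0 (no evidence of change)
    t = t.where(~(tested & (mean == 0) & (var_post == 0)), 0.0)

    p = pd.Series(np.nan, index=block.index)
    fin = tested & t.notna()
    norm_tail = fin & np.isinf(df_total)
    t_tail = fin & ~np.isinf(df_total)
    p[norm_tail] = 2.0 * stats.norm.sf(np.abs(t[norm_tail]))
    p[t_tail] = 2.0 * stats.t.sf(np.abs(t[t_tail]), df_total[t_tail])
    p = p.clip(lower=np.nextafter(0, 1), upper=1.0)
    p = p.where(fin)

    out = pd.DataFrame(
        {
            "n": n,
            "mean": mean,
            "var": var,
            "df": df,
            "var_post": var_post,
            "t": t.where(fin),
            "p": p,
            "df_total": df_total,
            "tested": tested,
        }
    )
    out.attrs["df_prior"] = d0
    out.attrs["var_prior"] = s0
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} p_(j) * m / j`` capped at 1, returned in the
    input order.  Ties in p receive equal q.  Input p-values must lie in
    (0, 1]; NaNs are not accepted (filter untested proteins first).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_changes(
    quant: QuantMatrix,
    criteria: FilterCriteria | None = None,
    conditions: Sequence[tuple[str, str, int]] | None = None,
    q_cutoff: float = 0.05,
    test_consistent_only: bool = True,
) -> dict[tuple[str, str, int], pd.DataFrame]:
    """Full differential pipeline, per condition.

    Normalize, filter for consistency, run the moderated test (by default
    on the consistent proteins only, matching the workflow in which only
    filtered NSP changes enter statistical analysis), and BH-adjust within
    the tested set.  Returns one DataFrame per condition combining the
    filter summary with ``t``, ``p``, ``q`` and ``significant``
    (``q < q_cutoff``; implies consistent when ``test_consistent_only``).
    """
    criteria = criteria or FilterCriteria()
    ratios = normalize_log_ratios(quant, min_ratio_count=criteria.min_ratio_count)
    if conditions is None:
        conditions = ratios.conditions()
    results = {}
    for cond in conditions:
        calls = filter_consistent(ratios, criteria, cond)
        calls["t"] = np.nan
        calls["p"] = np.nan
        calls["q"] = np.nan
        calls["significant"] = False
        subset = calls.index[calls["consistent"]] if test_consistent_only else calls.index
        block = ratios.condition_values(cond).loc[subset]
        testable = block.notna().sum(axis=1) >= 2
        if testable.sum() >= 10:
            st = moderated_test(block[testable])
            calls.loc[st.index, ["t", "p"]] = st[["t", "p"]].to_numpy()
            ok = st["p"].notna()
            q = bh_adjust(st.loc[ok, "p"].to_numpy())
            calls.loc[st.index[ok], "q"] = q
            calls["significant"] = calls["q"] < q_cutoff
        results[cond] = calls
    return results
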