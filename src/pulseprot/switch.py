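"""Repulsion-versus-attraction switch analysis.

Each guidance cue is repulsive under baseline second-messenger conditions
and becomes attractive when co-applied with its modulator (Tautomycin for
Netrin-1, Sp-cAMP for BDNF, 8-Br-cGMP for Sema3A).  This module compares
a cue's repulsive and attractive nascent-proteome responses:

* the *common regulated set*: proteins quantified in more than half of
  the replicates with an absolute average log2 ratio above 0.30 in both
  conditions;
* concordance: within the common set, a protein changes in the
  *opposite* direction when the signs of its repulsive and attractive
  averages differ, and in the *same* direction otherwise;
* summary fractions and within-subset Pearson correlations per cue, with
  max and unweighted-mean aggregates across cues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "SwitchThresholds",
    "SwitchPair",
    "ConcordanceSummary",
    "common_regulated_set",
    "classify_concordance",
    "switch_summary",
    "condition_profile",
]


@dataclass(frozen=True)
class SwitchThresholds:
    """Membership thresholds for the common regulated set.

    ``min_fraction`` is the replicate-quantification fraction (strict >,
    the same meaning as the consistency filter's first criterion);
    ``min_abs_ratio`` bounds the absolute average log2 ratio (strict >).
    """

    min_fraction: float = 0.5
    min_abs_ratio: float = 0.30


@dataclass
class SwitchPair:
    """One cue's repulsive/attractive comparison table.

    ``table`` is indexed by the common regulated proteins with columns
    ``avg_repulsive``, ``avg_attractive``, ``frac_repulsive``,
    ``frac_attractive`` and ``label`` in {"opposite", "same"}.
    """

    cue: str
    thresholds: SwitchThresholds
    table: pd.DataFrame

    @property
    def n_common(self) -> int:
        return len(self.table)


def condition_profile(
    calls: dict[tuple[str, str, int], pd.DataFrame],
    cue: str,
    modulator: str,
    pulses: list[int] | None = None,
) -> pd.DataFrame:
    """Time-averaged mean and quantification fraction for one condition.

    Averages the per-time-point means (and fractions) over the requested
    pulse durations; when ``pulses`` is None all available time points of
    the condition are used.  Missing time points are left out of the
    average per protein.
    """
    avail = sorted(p for (c, m, p) in calls if c == cue and m == modulator)
    if pulses is not None:
        avail = [p for p in avail if p in pulses]
    if not avail:
        raise ValidationError(f"no conditions for cue={cue!r}, modulator={modulator!r}")
    means = pd.DataFrame({p: calls[(cue, modulator, p)]["mean"] for p in avail})
    fracs = pd.DataFrame({p: calls[(cue, modulator, p)]["frac_quantified"] for p in avail})
    return pd.DataFrame({"mean": means.mean(axis=1), "frac_quantified": fracs.mean(axis=1)})


def common_regulated_set(
    repulsive: pd.DataFrame,
    attractive: pd.DataFrame,
    thresholds: SwitchThresholds | None = None,
    cue: str = "",
) -> SwitchPair:
    """Proteins regulated in both the repulsive and the attractive condition.

    Both inputs are protein-indexed DataFrames with columns ``mean`` and
    ``frac_quantified`` (as returned by :func:`condition_profile`).
    Membership requires, in *both* conditions, a quantification fraction
    strictly above ``min_fraction`` and an absolute average strictly above
    ``min_abs_ratio``.
    """
    thresholds = thresholds or SwitchThresholds()
    joined = repulsive[["mean", "frac_quantified"]].join(
        attractive[["mean", "frac_quantified"]],
        how="inner",
        lsuffix="_rep",
        rsuffix="_att",
    )

    def ok(mean: pd.Series, frac: pd.Series) -> pd.Series:
        return (
            mean.notna()
            & frac.notna()
            & (frac > thresholds.min_fraction)
            & (mean.abs() > thresholds.min_abs_ratio)
        )

    member = ok(joined["mean_rep"], joined["frac_quantified_rep"]) & ok(
        joined["mean_att"], joined["frac_quantified_att"]
    )
    table = joined[member].rename(
        columns={
            "mean_rep": "avg_repulsive",
            "mean_att": "avg_attractive",
            "frac_quantified_rep": "frac_repulsive",
            "frac_quantified_att": "frac_attractive",
        }
    )
    pair = SwitchPair(cue=cue, thresholds=thresholds, table=table)
    pair.table["label"] = classify_concordance(pair)
    return pair


def classify_concordance(pair: SwitchPair) -> pd.Series:
    """Per-protein label: "opposite" iff the two averages disagree in sign.

    Equivalent to ``sign(avg_repulsive * avg_attractive) < 0``; a zero
    average cannot occur in the common set (|avg| > 0.30 is required).
    """
    t = pair.table
    opposite = np.sign(t["avg_repulsive"]) != np.sign(t["avg_attractive"])
    return pd.Series(np.where(opposite, "opposite", "same"), index=t.index, dtype=object)


@dataclass
class ConcordanceSummary:
    """Per-cue concordance counts/fractions/correlations plus aggregates.

    ``per_cue`` columns: ``n_common``, ``n_opposite``, ``n_same``,
    ``frac_opposite``, ``frac_same``, ``pcc_opposite``, ``pcc_same``
    (within-subset Pearson correlations of attractive vs repulsive
    averages; NaN when a subset has fewer than 3 proteins).
    ``aggregate``: max and unweighted mean of ``frac_opposite`` and mean
    of the subset PCCs across cues.
    """

    per_cue: pd.DataFrame
    aggregate: pd.Series


def switch_summary(pairs: dict[str, SwitchPair] | list[SwitchPair]) -> ConcordanceSummary:
    """Summarize repulsion/attraction concordance across cues."""
    if isinstance(pairs, dict):
        pairs = list(pairs.values())
    if not pairs or all(p.n_common == 0 for p in pairs):
        raise ValidationError("at least one cue must have a non-empty common set")
    rows = {}
    for pair in pairs:
        t = pair.table
        labels = t["label"]
        n = len(t)
        n_opp = int((labels == "opposite").sum())
        n_same = n - n_opp

        def subset_pcc(name: str) -> float:
            sub = t[labels == name]
            if len(sub) < 3:
                return float("nan")
            return float(stats.pearsonr(sub["avg_repulsive"], sub["avg_attractive"]).statistic)

        rows[pair.cue] = {
            "n_common": n,
            "n_opposite": n_opp,
            "n_same": n_same,
            "frac_opposite": n_opp / n if n else float("nan"),
            "frac_same": n_same / n if n else float("nan"),
            "pcc_opposite": subset_pcc("opposite"),
            "pcc_same": subset_pcc("same"),
        }
    per_cue = pd.DataFrame.from_dict(rows, orient="index")
    aggregate = pd.Series(
        {
            "frac_opposite_max": per_cue["frac_opposite"].max(),
            "frac_opposite_mean": per_cue["frac_opposite"].mean(),
            "frac_same_mean": per_cue["frac_same"].mean(),
            "pcc_opposite_mean": per_cue["pcc_opposite"].mean(),
            "pcc_same_mean": per_cue["pcc_same"].mean(),
        }
    )
    return ConcordanceSummary(per_cue=per_cue, aggregate=aggregate)
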