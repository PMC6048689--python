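"""Cross-time and cross-cue signature analysis.

Given per-condition differential summaries (mean normalized log2(H/M),
replicate quantification fractions and consistency flags), this module
derives cue signatures and compares them:

* time-averaged per-cue profiles (unweighted mean over available time
  points);
* signed regulated sets (consistent and |mean| > 0.3, carrying direction);
* overlaps between signed sets, with direction agreement required for
  shared membership — a sign flip between sets counts as "opposite";
* the SD-based partition of proteins into "common" (cross-cue SD < 0.5)
  and "different" (SD >= 0.5) responses;
* condition similarity: pairwise Pearson correlation on pairwise-complete
  proteins and PCA (conditions as observations) on the complete submatrix;
* average-linkage (UPGMA) hierarchical clustering on Euclidean distances;
* generic over-representation of user-supplied annotation categories by a
  one-sided hypergeometric test with BH correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .errors import ValidationError

__all__ = [
    "CueProfile",
    "OverlapResult",
    "SimilarityResult",
    "LinkageTree",
    "average_time_profiles",
    "regulated_set",
    "overlap_sets",
    "sd_partition",
    "condition_similarity",
    "hcluster_average_linkage",
    "enrichment_overrepresentation",
]


@dataclass
class CueProfile:
    """Per-cue time-course and time-averaged profile.

    ``time_means`` is proteins x pulse-minutes; ``avg`` averages the
    available (non-missing) time points per protein, unweighted;
    companion frames carry replicate provenance and consistency flags.
    """

    cue: str
    modulator: str
    time_means: pd.DataFrame
    avg: pd.Series
    frac_quantified: pd.DataFrame
    consistent: pd.DataFrame

    @property
    def consistent_any(self) -> pd.Series:
        """Consistent at one or more time points."""
        return self.consistent.fillna(False).any(axis=1)


def average_time_profiles(
    calls: dict[tuple[str, str, int], pd.DataFrame],
    cue: str,
    modulator: str = "none",
) -> CueProfile:
    """Collapse a cue's per-time-point differential calls into one profile.

    ``calls`` maps condition keys ``(cue, modulator, pulse_minutes)`` to
    the per-protein summary of :func:`pulseprot.differential.call_changes`
    (columns ``mean``, ``frac_quantified``, ``consistent``).  Missing
    time-point means are simply left out of the average.
    """
    pulses = sorted(p for (c, m, p) in calls if c == cue and m == modulator)
    if not pulses:
        raise ValidationError(f"no conditions for cue={cue!r}, modulator={modulator!r}")
    means, fracs, cons = {}, {}, {}
    for p in pulses:
        df = calls[(cue, modulator, p)]
        means[p] = df["mean"]
        fracs[p] = df["frac_quantified"]
        cons[p] = df["consistent"]
    time_means = pd.DataFrame(means)
    return CueProfile(
        cue=cue,
        modulator=modulator,
        time_means=time_means,
        avg=time_means.mean(axis=1),
        frac_quantified=pd.DataFrame(fracs),
        consistent=pd.DataFrame(cons),
    )


def regulated_set(
    means: pd.Series,
    flags: pd.Series | None = None,
    threshold: float = 0.3,
) -> dict[str, int]:
    """Signed regulated membership: ``{protein: +1 or -1}``.

    A protein is a member iff its consistency flag holds (all True when
    ``flags`` is None) and ``|mean| > threshold`` (strict, so a mean of
    exactly 0.3 — or 0.29 — is excluded).
    """
    if flags is None:
        flags = pd.Series(True, index=means.index)
    flags = flags.reindex(means.index).fillna(False).astype(bool)
    member = flags & (means.abs() > threshold)
    return {str(p): int(np.sign(means[p])) for p in means.index[member]}


@dataclass
class OverlapResult:
    """Signed-set overlap across groups (time points or cues).

    ``per_protein``: one row per protein in the union, with each group's
    sign (0 = not a member), the membership ``region`` (sorted tuple of
    group names) and ``agreement`` in {"single", "same", "opposite"}.
    ``region_counts``: rows (region, agreement, count); regions of size 1
    are the exclusive ("unique per group") sets.
    """

    groups: list[str]
    per_protein: pd.DataFrame
    region_counts: pd.DataFrame

    def exclusive(self, group: str) -> list[str]:
        """Proteins regulated in exactly this group (unique-per-cue set)."""
        mask = self.per_protein["region"] == (group,)
        return list(self.per_protein.index[mask])

    def shared(self, *groups: str, same_direction: bool = True) -> list[str]:
        """Proteins in exactly these groups, optionally direction-concordant."""
        region = tuple(sorted(groups))
        mask = self.per_protein["region"] == region
        if same_direction:
            mask &= self.per_protein["agreement"].isin(["single", "same"])
        return list(self.per_protein.index[mask])


def overlap_sets(sets: dict[str, dict[str, int]]) -> OverlapResult:
    """All intersection regions of two or more signed membership sets.

    Shared membership requires direction agreement; proteins present in
    several sets with conflicting signs fall in the same region but are
    labelled "opposite" and excluded from direction-concordant sharing.
    """
    if len(sets) < 2:
        raise ValidationError("need at least two sets to overlap")
    groups = list(sets)
    union = sorted(set(itertools.chain.from_iterable(sets.values())))
    rows = []
    for protein in union:
        signs = {g: sets[g].get(protein, 0) for g in groups}
        present = tuple(sorted(g for g in groups if signs[g] != 0))
        nz = {signs[g] for g in present}
        if len(present) == 1:
            agreement = "single"
        elif len(nz) == 1:
            agreement = "same"
        else:
            agreement = "opposite"
        rows.append({**signs, "region": present, "agreement": agreement})
    per_protein = pd.DataFrame(rows, index=pd.Index(union, name="protein_id"))
    if union:
        counts = (
            per_protein.groupby(["region", "agreement"], sort=True)
            .size()
            .rename("count")
            .reset_index()
        )
    else:
        counts = pd.DataFrame(columns=["region", "agreement", "count"])
    return OverlapResult(groups=groups, per_protein=per_protein, region_counts=counts)


def sd_partition(
    cue_averages: pd.DataFrame,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Partition proteins by the spread of their per-cue average changes.

    ``cue_averages`` is proteins x cues (typically three time-averaged cue
    profiles).  Proteins quantified for all cues get the sample SD (n-1)
    of their cue averages and the label "common" (SD < threshold) or
    "different" (SD >= threshold; the boundary value goes to "different"
    by convention); proteins missing any cue are "unassigned".
    """
    complete = cue_averages.notna().all(axis=1)
    sd = cue_averages.std(axis=1, ddof=1)
    label = pd.Series("unassigned", index=cue_averages.index, dtype=object)
    label[complete & (sd < threshold)] = "common"
    label[complete & (sd >= threshold)] = "different"
    return pd.DataFrame({"sd": sd.where(complete), "label": label})


@dataclass
class SimilarityResult:
    """Pairwise condition similarity and PCA.

    ``pcc``: symmetric condition x condition Pearson matrix computed on
    pairwise-complete proteins (NaN when a pair shares fewer than 3);
    ``scores``: condition scores on the principal components of the
    column-centered complete-protein submatrix (SVD); ``explained``: the
    per-component explained-variance fractions (summing to 1).
    """

    pcc: pd.DataFrame
    scores: pd.DataFrame
    explained: np.ndarray
    n_proteins_used: int


def condition_similarity(profiles: pd.DataFrame) -> SimilarityResult:
    """Similarity of condition signatures (conditions x proteins input).

    PCC uses pairwise-complete proteins per condition pair; PCA requires a
    full matrix and therefore uses the complete-protein submatrix
    (conditions as observations, protein columns centered), with scores
    obtained by singular value decomposition.  No imputation.
    """
    if profiles.shape[0] < 2:
        raise ValidationError("need at least 2 conditions")
    pcc = profiles.T.corr(min_periods=3)
    np.fill_diagonal(pcc.to_numpy(), 1.0)

    complete = profiles.dropna(axis=1)
    n_used = complete.shape[1]
    k = min(profiles.shape[0], max(n_used, 1))
    if n_used == 0:
        scores = pd.DataFrame(index=profiles.index)
        explained = np.array([])
    else:
        X = complete.to_numpy(dtype=float)
        X = X - X.mean(axis=0, keepdims=True)
        U, S, _ = np.linalg.svd(X, full_matrices=False)
        scores = pd.DataFrame(
            U * S,
            index=profiles.index,
            columns=[f"PC{i + 1}" for i in range(len(S))],
        )
        total = (S**2).sum()
        explained = (S**2) / total if total > 0 else np.zeros_like(S)
    return SimilarityResult(pcc=pcc, scores=scores, explained=explained, n_proteins_used=n_used)


@dataclass
class LinkageTree:
    """Average-linkage merge sequence over items.

    ``linkage``: SciPy linkage matrix (pairs, heights, cluster sizes);
    ``labels``: item names in input order.  Merge heights are
    non-decreasing (UPGMA on a fixed dissimilarity is monotone).
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]


def hcluster_average_linkage(
    matrix: pd.DataFrame,
    axis: str = "rows",
) -> tuple[LinkageTree, list[str]]:
    """UPGMA clustering on Euclidean distances.

    Rows (or columns, with ``axis="columns"``) containing missing values
    are dropped before clustering — complete rows only, as desktop
    proteomics tools require — and returned as the second element for
    logging.  Fewer than 2 complete items is an error.
    """
    if axis == "columns":
        matrix = matrix.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    complete = matrix.dropna(axis=0)
    dropped = [str(i) for i in matrix.index.difference(complete.index)]
    if complete.shape[0] < 2:
        raise ValidationError("need at least 2 complete items to cluster")
    Z = hierarchy.linkage(complete.to_numpy(dtype=float), method="average", metric="euclidean")
    return LinkageTree(linkage=Z, labels=[str(i) for i in complete.index]), dropped


def enrichment_overrepresentation(
    selection: set[str] | list[str],
    annotation: dict[str, set[str] | list[str]],
    universe: set[str] | list[str],
    min_category_count: int = 3,
    ease: bool = False,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of annotation categories.

    For a category of size K (within the universe of size N) and a
    selection of size n with overlap k, the p-value is the upper
    hypergeometric tail P(X >= k).  Only categories with
    ``k >= min_category_count`` are tested (pathway-count cutoff); BH
    adjustment runs across the tested categories.  ``ease=True`` applies
    the conservative EASE variant, scoring k-1 overlapping proteins
    (non-default).
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("universe is empty")
    selection = set(selection)
    if not selection <= universe:
        raise ValidationError("selection must be a subset of the universe")
    N, n = len(universe), len(selection)
    rows = []
    for cat, members in annotation.items():
        members = set(members) & universe
        K = len(members)
        k = len(members & selection)
        if k < min_category_count:
            continue
        k_eff = k - 1 if ease else k
        p = float(stats.hypergeom.sf(k_eff - 1, N, K, n))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append({"category": cat, "N": N, "K": K, "n": n, "k": k, "p": p})
    out = pd.DataFrame(rows, columns=["category", "N", "K", "n", "k", "p"])
    if len(out):
        from .differential import bh_adjust

        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
    return out
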