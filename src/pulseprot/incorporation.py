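"""Basal nascent-proteome statistics.

In a pulsed-SILAC sample the medium (M) channel carries protein synthesized
during the pulse under control conditions and the light (L) channel the
pre-existing pool, so ``M/(M+L)`` is the fraction of a protein's total
signal that was newly made during the pulse, and ``(M/(M+L)) / pulse
duration`` is the per-minute basal incorporation rate.  Basal incorporation
is small — of order 1% of total signal for a 5-minute pulse — so both the
raw fraction and the per-minute rate are reported explicitly.

A protein counts as a detected NSP (newly synthesized protein) in a sample
when its M intensity is present; no imputation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SelectionError
from .experiment import QuantMatrix, SampleInfo

__all__ = [
    "IncorporationResult",
    "CorrelationReport",
    "incorporation_rates",
    "abundance_ratio_correlations",
]


@dataclass
class IncorporationResult:
    """Basal incorporation summary.

    ``per_protein`` has columns ``fraction`` (mean M/(M+L) over the selected
    samples), ``rate_per_min`` (mean fraction / pulse minutes) and
    ``detected`` (M present in at least one selected sample).  Proteins with
    no usable M+L signal in any selected sample are absent and listed in
    ``skipped`` with a reason.  Summary medians are taken over detected NSPs.
    """

    per_protein: pd.DataFrame
    nsp_counts: pd.Series
    median_fraction: float
    median_rate_per_min: float
    skipped: pd.Series

    @property
    def n_detected(self) -> int:
        return int(self.per_protein["detected"].sum())


def _select_samples(quant: QuantMatrix, samples) -> list[SampleInfo]:
    if samples is None:
        chosen = [s for s in quant.samples if s.is_basal]
        if not chosen:
            raise SelectionError(
                "no basal (cue = none) samples in the design; pass an explicit selection"
            )
        return chosen
    if callable(samples):
        chosen = [s for s in quant.samples if samples(s)]
    else:
        wanted = set(samples)
        chosen = [s for s in quant.samples if s.sample_id in wanted]
        missing = wanted - {s.sample_id for s in chosen}
        if missing:
            raise SelectionError(f"unknown sample ids in selection: {sorted(missing)}")
    if not chosen:
        raise SelectionError("sample selection is empty")
    return chosen


def incorporation_rates(quant: QuantMatrix, samples=None) -> IncorporationResult:
    """Per-protein basal incorporation fractions and per-minute rates.

    Parameters
    ----------
    quant : QuantMatrix
    samples : None, callable or list of sample IDs
        Samples to use.  Default: all basal (cue = none) samples.  The M
        channel carries control-condition synthesis in every sample, so an
        explicit selection may be passed when no dedicated basal samples
        exist.

    Notes
    -----
    Per (protein, sample): fraction = M/(M+L) over cells where both
    channels were measured (an explicit M = 0 with L > 0 gives fraction 0;
    a *missing* M is non-detection, not a zero, so the cell is unusable
    and simply excluded).  Per-protein values average the usable cells;
    the per-minute rate divides each cell's fraction by that sample's
    pulse duration before averaging.
    """
    chosen = _select_samples(quant, samples)
    sids = [s.sample_id for s in chosen]
    M = quant.intensity("M")[sids]
    L = quant.intensity("L")[sids]

    usable = M.notna() & L.notna() & ((M + L) > 0)
    total = M + L
    frac = (M / total).where(usable)
    pulse = pd.Series({s.sample_id: float(s.pulse_minutes) for s in chosen})
    rate = frac.div(pulse, axis=1)

    detected_cell = M.notna() & (M > 0)
    any_usable = usable.any(axis=1)
    per_protein = pd.DataFrame(
        {
            "fraction": frac.mean(axis=1),
            "rate_per_min": rate.mean(axis=1),
            "detected": detected_cell.any(axis=1),
            "n_samples_used": usable.sum(axis=1),
        }
    )[any_usable]

    skipped = pd.Series(
        "no selected sample with both M and L measured (or M+L = 0)",
        index=quant.protein_ids[~any_usable],
        dtype=object,
    )
    nsp_counts = detected_cell.sum(axis=0)
    detected = per_protein[per_protein["detected"]]
    return IncorporationResult(
        per_protein=per_protein,
        nsp_counts=nsp_counts,
        median_fraction=float(detected["fraction"].median()),
        median_rate_per_min=float(detected["rate_per_min"].median()),
        skipped=skipped,
    )


@dataclass
class CorrelationReport:
    """Abundance correlations of the basal nascent proteome.

    ``r_abundance_vs_nsp``: correlation of log pre-existing abundance with
    log M (NSP) intensity — positive in real data (low-abundance proteins
    sit near the detection floor).  ``r_abundance_vs_ratio``: correlation of
    log(M/L) with log abundance — negative in real data, meaning the basal
    translation rate is roughly constant across the abundance range.
    """

    method: str
    r_abundance_vs_nsp: float
    n_abundance_vs_nsp: int
    r_abundance_vs_ratio: float
    n_abundance_vs_ratio: int


def abundance_ratio_correlations(
    quant: QuantMatrix, samples=None, method: str = "pearson"
) -> CorrelationReport:
    """Correlate basal NSP signal and M/L ratio with pre-existing abundance.

    Logs are natural; the base does not affect either correlation.
    Requires the QuantMatrix ``abundance`` column and at least 3 complete
    pairs per correlation.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if quant.abundance is None:
        raise SelectionError("QuantMatrix has no abundance column")
    chosen = _select_samples(quant, samples)
    sids = [s.sample_id for s in chosen]

    log_ab = np.log(quant.abundance.where(quant.abundance > 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        log_M = np.log(quant.intensity("M")[sids]).mean(axis=1)
        log_ML = np.log(quant.field("ratio_ML")[sids]).mean(axis=1)

    corr = stats.pearsonr if method == "pearson" else stats.spearmanr

    def paired(a: pd.Series, b: pd.Series) -> tuple[float, int]:
        ok = a.notna() & b.notna()
        n = int(ok.sum())
        if n < 3:
            raise SelectionError(f"fewer than 3 complete pairs (got {n})")
        # a constant margin (e.g. perfectly constant M/L) carries no
        # association: report 0 rather than the undefined coefficient
        if np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
            return 0.0, n
        r = float(corr(a[ok], b[ok]).statistic)
        return r, n

    r1, n1 = paired(log_ab, log_M)
    r2, n2 = paired(log_ab, log_ML)
    return CorrelationReport(
        method=method,
        r_abundance_vs_nsp=r1,
        n_abundance_vs_nsp=n1,
        r_abundance_vs_ratio=r2,
        n_abundance_vs_ratio=n2,
    )
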