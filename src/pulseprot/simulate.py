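"""Synthetic pSILAC quantification tables and growth-cone images.

The pulse simulator emulates the structure of a triple-SILAC guidance-cue
experiment with known ground truth:

* per-protein pre-existing abundance is log-normal (MS intensities span
  several orders of magnitude);
* the control-channel (M) signal is tied to the light channel through a
  per-protein basal incorporation fraction ``kappa`` of order 1% per 5-min
  pulse, with log-normal protein-to-protein jitter and a negative coupling
  to abundance — reproducing the qualitative structure of real data, where
  NSP intensity correlates positively, and the M/L ratio negatively, with
  pre-existing abundance;
* the stimulated channel is ``H = M * 2**(effect + noise)`` per replicate,
  with a designed fraction of proteins truly up-/down-regulated by a fixed
  log2 effect and Gaussian replicate noise (a fixed-effect model, matching
  the assumptions of the moderated one-sample t);
* detection of each channel intensity follows a logistic model in log
  intensity, so missingness decreases monotonically with abundance.

The image simulator draws an elliptical growth-cone ROI with a controllable
multiplicative intensity asymmetry ``g`` on the gradient-facing ("near")
half, on top of a flat background, together with a uniform brightfield
channel and the bisection/gradient geometry used by the polarity module.

Both generators are deterministic under a fixed seed; all random streams
are derived from one master seed via ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError, GeometryError
from .experiment import QuantMatrix, SampleInfo
from .polarity import GrowthConeImage

__all__ = [
    "SimConfig",
    "ImageSimConfig",
    "simulate_pulse_experiment",
    "simulate_study",
    "simulate_growth_cone_image",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the pulse-experiment simulator.

    Attributes
    ----------
    n_proteins, n_replicates : int
        Problem size; the study used 3-5 biological replicates per cue.
    pi_up, pi_down : float
        Fractions of truly up-/down-regulated proteins (``pi_up + pi_down <= 1``).
    delta : float
        True absolute log2(H/M) effect for regulated proteins.
    sigma_rep : float
        Replicate noise SD in log2 units.
    kappa : float
        Median basal incorporation fraction M/(M+L) per pulse; 0.014 by
        default (of order 1% per 5-min pulse).
    sigma_kappa : float
        Log-normal protein-to-protein jitter SD of kappa (natural-log units).
    abundance_slope : float
        Slope of log kappa vs centered log abundance; negative values give
        the negative abundance <-> M/L correlation seen in real data.
    mu_abund, sigma_abund : float
        Log-normal abundance parameters (natural-log intensity units).
    sigma_meas : float
        Per-replicate multiplicative measurement noise on channel
        intensities (natural-log SD).
    missing_midpoint, missing_slope : float
        Logistic detection model: P(detect) = expit(slope * (ln I - midpoint)).
    cue, modulator, pulse_minutes : condition of the simulated samples.
    seed : int
        Master seed; fixed seed implies byte-identical output.
    """

    n_proteins: int = 2000
    n_replicates: int = 3
    pi_up: float = 0.0
    pi_down: float = 0.0
    delta: float = 0.0
    sigma_rep: float = 0.5
    kappa: float = 0.014
    sigma_kappa: float = 0.5
    abundance_slope: float = -0.3
    mu_abund: float = 16.0
    sigma_abund: float = 1.5
    sigma_meas: float = 0.1
    missing_midpoint: float = 8.5
    missing_slope: float = 1.0
    cue: str = "Netrin1"
    modulator: str = "none"
    pulse_minutes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ConfigError("n_proteins and n_replicates must be positive")
        if not (0 <= self.pi_up <= 1 and 0 <= self.pi_down <= 1):
            raise ConfigError("pi_up and pi_down must lie in [0, 1]")
        if self.pi_up + self.pi_down > 1:
            raise ConfigError("pi_up + pi_down must not exceed 1")
        if self.delta < 0:
            raise ConfigError("delta must be >= 0")
        if self.sigma_rep <= 0:
            raise ConfigError("sigma_rep must be > 0")
        if not (0 < self.kappa < 1):
            raise ConfigError("kappa must lie in (0, 1)")


def _baseline(config: SimConfig, seq: np.random.SeedSequence):
    """Shared per-protein quantities: abundance and basal incorporation."""
    s_ab, s_kap = seq.spawn(2)
    rng_ab = np.random.default_rng(s_ab)
    rng_kap = np.random.default_rng(s_kap)
    log_abund = rng_ab.normal(config.mu_abund, config.sigma_abund, config.n_proteins)
    log_kappa = (
        np.log(config.kappa)
        + config.abundance_slope * (log_abund - config.mu_abund)
        + rng_kap.normal(0.0, config.sigma_kappa, config.n_proteins)
    )
    kappa = np.clip(np.exp(log_kappa), 1e-6, 0.5)
    return np.exp(log_abund), kappa


def _ratio_counts(rng: np.random.Generator, log_intensity: np.ndarray, midpoint: float):
    """Peptide ratio counts: higher for brighter signals, occasionally 1."""
    lam = np.clip(2.2 * (log_intensity - midpoint), 0.05, 20.0)
    lam = np.nan_to_num(lam, nan=0.05)  # undetected cells: count zeroed later
    return 1 + rng.poisson(lam)


def simulate_pulse_experiment(config: SimConfig) -> tuple[QuantMatrix, pd.DataFrame]:
    """Simulate one condition of a pulse experiment.

    Returns
    -------
    quant : QuantMatrix
        ``n_replicates`` samples of the configured condition, with L/M/H
        intensities, H/M and M/L ratios, ratio counts, missingness and a
        per-protein ``abundance`` column (the noiseless light-channel level).
    truth : DataFrame
        Ground truth per protein: ``true_class`` in {up, down, null},
        ``true_effect`` (signed log2, 0 iff null) and ``true_kappa``.
    """
    seq = np.random.SeedSequence(config.seed)
    base_seq, cond_seq = seq.spawn(2)
    abundance, kappa = _baseline(config, base_seq)
    return _simulate_condition(config, abundance, kappa, cond_seq)


def simulate_study(
    config: SimConfig,
    conditions: Sequence[tuple[str, str, int]],
) -> tuple[QuantMatrix, dict[tuple[str, str, int], pd.DataFrame]]:
    """Simulate several conditions over a shared protein panel.

    Per-protein abundance and basal incorporation are drawn once from the
    master seed; regulation classes, replicate noise and missingness are
    drawn independently per condition from derived substreams, so different
    cues have distinct (randomly overlapping) sets of regulated proteins.
    """
    seq = np.random.SeedSequence(config.seed)
    base_seq, *cond_seqs = seq.spawn(1 + len(conditions))
    abundance, kappa = _baseline(config, base_seq)
    quants, truths = [], {}
    for (cue, modulator, pulse), cseq in zip(conditions, cond_seqs):
        cfg = replace(config, cue=cue, modulator=modulator, pulse_minutes=pulse)
        q, t = _simulate_condition(cfg, abundance, kappa, cseq)
        quants.append(q)
        truths[(cue, modulator, pulse)] = t
    samples = [s for q in quants for s in q.samples]
    fields = {
        name: pd.concat([q.field(name) for q in quants], axis=1)
        for name in quants[0]._fields
    }
    return QuantMatrix(samples, fields, quants[0].abundance), truths


def _simulate_condition(
    config: SimConfig,
    abundance: np.ndarray,
    kappa: np.ndarray,
    seq: np.random.SeedSequence,
) -> tuple[QuantMatrix, pd.DataFrame]:
    n, r = config.n_proteins, config.n_replicates
    s_cls, s_meas, s_eps, s_det, s_cnt = seq.spawn(5)
    rng_cls = np.random.default_rng(s_cls)
    rng_meas = np.random.default_rng(s_meas)
    rng_eps = np.random.default_rng(s_eps)
    rng_det = np.random.default_rng(s_det)
    rng_cnt = np.random.default_rng(s_cnt)

    classes = rng_cls.choice(
        np.array(["up", "down", "null"]),
        size=n,
        p=[config.pi_up, config.pi_down, 1.0 - config.pi_up - config.pi_down],
    )
    effect = np.where(classes == "up", config.delta, 0.0) - np.where(
        classes == "down", config.delta, 0.0
    )

    L0 = abundance
    M0 = L0 * kappa / (1.0 - kappa)  # so that M/(M+L) == kappa exactly

    # realized per-replicate intensities (proteins x replicates)
    mnoise = rng_meas.normal(0.0, config.sigma_meas, size=(n, r, 2))
    L = L0[:, None] * np.exp(mnoise[:, :, 0])
    M = M0[:, None] * np.exp(mnoise[:, :, 1])
    eps = rng_eps.normal(0.0, config.sigma_rep, size=(n, r))
    H = M * 2.0 ** (effect[:, None] + eps)

    # logistic detection per channel, driven by the protein's *expected*
    # channel intensity: missingness is abundance-dependent but ignorable
    # given the protein (no coupling to the replicate noise, so ratio
    # statistics stay unbiased under the null)
    def detect(expected: np.ndarray, shape: tuple) -> np.ndarray:
        p = expit(config.missing_slope * (np.log(expected) - config.missing_midpoint))
        return rng_det.random(shape) < p[:, None]

    L = np.where(detect(L0, L.shape), L, np.nan)
    M = np.where(detect(M0, M.shape), M, np.nan)
    H = np.where(detect(M0 * 2.0**effect, H.shape), H, np.nan)

    ratio_HM = H / M
    ratio_ML = M / L
    # peptide ratio counts reflect a protein's peptide coverage: driven by
    # the expected (not realized) intensity of the dimmer parent channel
    exp_HM = np.log(np.fmin(M0 * 2.0**effect, M0))[:, None] * np.ones((1, r))
    exp_ML = np.log(np.fmin(M0, L0))[:, None] * np.ones((1, r))
    cnt_HM = _ratio_counts(rng_cnt, exp_HM, config.missing_midpoint)
    cnt_ML = _ratio_counts(rng_cnt, exp_ML, config.missing_midpoint)
    cnt_HM = np.where(np.isnan(ratio_HM), 0, cnt_HM)
    cnt_ML = np.where(np.isnan(ratio_ML), 0, cnt_ML)

    proteins = pd.Index([f"P{i:05d}" for i in range(n)], name="protein_id")
    samples = [
        SampleInfo(
            cue=config.cue,
            modulator=config.modulator,
            pulse_minutes=config.pulse_minutes,
            replicate_id=f"r{j + 1}",
        )
        for j in range(r)
    ]
    sids = [s.sample_id for s in samples]

    def wide(a: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(a, index=proteins, columns=sids)

    fields = {
        "intensity_L": wide(L),
        "intensity_M": wide(M),
        "intensity_H": wide(H),
        "ratio_HM": wide(ratio_HM),
        "ratio_ML": wide(ratio_ML),
        "ratio_count_HM": wide(cnt_HM.astype(float)),
        "ratio_count_ML": wide(cnt_ML.astype(float)),
    }
    quant = QuantMatrix(samples, fields, pd.Series(L0, index=proteins, name="abundance"))
    truth = pd.DataFrame(
        {"true_class": classes, "true_effect": effect, "true_kappa": kappa},
        index=proteins,
    )
    return quant, truth


# ---------------------------------------------------------------------------
# Growth-cone image simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageSimConfig:
    """Parameters of the synthetic growth-cone image.

    The ROI is an ellipse centered on the image; the gradient source sits
    ``source_distance`` pixels from the ROI center at ``gradient_angle``
    degrees (measured from the +x axis, y increasing with row index; the
    default 90 degrees places the source perpendicular to the shaft axis,
    as in a 90-degree gradient assay).  The shaft axis passes through the
    ROI center perpendicular to the source direction, so the near half is
    the gradient-facing half.  Fluorescence is ``base_intensity * g`` on
    the near half of the ROI and ``base_intensity`` on the far half, on top
    of ``background_level`` everywhere, plus Gaussian noise clipped at 0.
    The brightfield companion channel is uniform.
    """

    height: int = 96
    width: int = 128
    semi_axis_x: float = 40.0
    semi_axis_y: float = 28.0
    base_intensity: float = 100.0
    asymmetry: float = 1.0
    background_level: float = 10.0
    noise_sd: float = 0.0
    gradient_angle: float = 90.0
    source_distance: float = 70.0
    brightfield_level: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.asymmetry <= 0:
            raise ConfigError("asymmetry factor g must be > 0")
        if self.height < 8 or self.width < 8:
            raise ConfigError("image must be at least 8x8 pixels")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def simulate_growth_cone_image(config: ImageSimConfig) -> GrowthConeImage:
    """Render a synthetic growth cone with known near/far asymmetry.

    The ellipse center is placed at pixel coordinates
    ``((width-1)/2, (height-1)/2)`` so that for the default 90-degree
    geometry the rasterized ROI is exactly mirror-symmetric about the shaft
    line; with ``g = 1`` and zero noise the near/far ratio is exactly 1 and
    the center-of-mass shift is exactly zero.
    """
    h, w = config.height, config.width
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]  # pixel centers, 0-based

    roi = (
        ((xx - cx) / config.semi_axis_x) ** 2 + ((yy - cy) / config.semi_axis_y) ** 2
    ) <= 1.0
    if not roi.any():
        raise GeometryError("ROI ellipse rasterized to zero pixels")

    theta = np.deg2rad(config.gradient_angle)
    u = np.array([np.cos(theta), np.sin(theta)])  # toward the source
    source = np.array([cx, cy]) + config.source_distance * u
    # shaft axis through the center, perpendicular to the source direction
    v = np.array([-u[1], u[0]])
    span = float(max(h, w))
    p1 = (cx - span * v[0], cy - span * v[1])
    p2 = (cx + span * v[0], cy + span * v[1])

    # signed distance to the shaft line; positive on the source side
    signed = (xx - cx) * u[0] + (yy - cy) * u[1]
    factor = np.where(signed > 0, config.asymmetry, 1.0)
    factor = np.where(signed == 0, 1.0, factor)

    fluor = np.full((h, w), config.background_level, dtype=float)
    fluor[roi] += config.base_intensity * factor[roi]
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        fluor = fluor + rng.normal(0.0, config.noise_sd, size=(h, w))
    fluor = np.clip(fluor, 0.0, None)

    bright = np.full((h, w), config.brightfield_level, dtype=float)

    # background patch in the corner farthest from the source, clear of the ROI
    bg = np.zeros((h, w), dtype=bool)
    bg[2:10, 2:10] = True
    bg &= ~roi
    if not bg.any():
        raise GeometryError("background patch overlaps the ROI entirely")

    return GrowthConeImage(
        fluorescence=fluor,
        brightfield=bright,
        roi_mask=roi,
        background_mask=bg,
        shaft_axis=(p1, p2),
        gradient_source=(float(source[0]), float(source[1])),
    )
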