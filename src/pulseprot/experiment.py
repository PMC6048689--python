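"""Domain types and table I/O for pulsed-SILAC quantification experiments.

A pulsed-SILAC (pSILAC) sample carries three isotope channels per protein:
light (L, the pre-existing protein pool), medium (M, protein synthesized in
the control condition during the pulse; Lys4/Arg6) and heavy (H, protein
synthesized in the stimulated condition; Lys8/Arg10).  The H/M ratio compares
stimulated versus control synthesis of the same protein in the same run; the
M/L ratio relates newly synthesized to pre-existing protein.

This module defines the shared data backbone — :class:`SampleInfo`,
:class:`LabelTriplet` and :class:`QuantMatrix` — plus readers for
MaxQuant-style proteinGroups tables and a generic long-format table, a
design-table reader, and a round-trip-safe TSV writer.

Missing-value semantics: a zero in any MS intensity column is treated as
non-detection and mapped to NaN; a ratio is missing whenever either parent
channel is missing.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError, IntegrityError

__all__ = [
    "CUES",
    "MODULATORS",
    "CHANNELS",
    "SampleInfo",
    "LabelTriplet",
    "QuantMatrix",
    "parse_design",
    "parse_quant_table",
    "write_table",
]

#: Guidance cues used in the study (``none`` marks basal, unstimulated samples).
CUES = ("none", "Netrin1", "BDNF", "Sema3A")

#: Pharmacological modulators that convert repulsion to attraction:
#: Tautomycin (PP1 inhibitor, pairs with Netrin-1), Sp-cAMP (cAMP analog,
#: pairs with BDNF) and 8-Br-cGMP (cGMP agonist, pairs with Sema3A).
MODULATORS = ("none", "Tautomycin", "SpcAMP", "BrcGMP")

CHANNELS = ("L", "M", "H")

#: Per-(protein, sample) numeric fields stored in a QuantMatrix.
_FIELDS = (
    "intensity_L",
    "intensity_M",
    "intensity_H",
    "ratio_HM",
    "ratio_ML",
    "ratio_count_HM",
    "ratio_count_ML",
)


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for a single pSILAC MS sample.

    Parameters
    ----------
    cue : str
        Guidance cue, one of :data:`CUES`; ``"none"`` for basal samples.
    modulator : str
        Second-messenger modulator, one of :data:`MODULATORS`.  A modulator
        requires a cue (it converts that cue's repulsive response to
        attraction); ``modulator != "none"`` with ``cue == "none"`` is
        rejected.
    pulse_minutes : int
        Duration of the isotope pulse (5, 15 or 30 min in the study).
    replicate_id : str
        Biological-replicate label, unique within a condition.
    channel_scheme : str
        Which channel carries the stimulated sample; ``"H_stimulated"``
        (default) means H = stimulated, M = control.
    """

    cue: str
    modulator: str = "none"
    pulse_minutes: int = 5
    replicate_id: str = "r1"
    channel_scheme: str = "H_stimulated"

    def __post_init__(self) -> None:
        if self.cue not in CUES:
            raise DesignError(f"unknown cue {self.cue!r}; expected one of {CUES}")
        if self.modulator not in MODULATORS:
            raise DesignError(
                f"unknown modulator {self.modulator!r}; expected one of {MODULATORS}"
            )
        if not (isinstance(self.pulse_minutes, (int, np.integer)) and self.pulse_minutes > 0):
            raise DesignError(
                f"pulse_minutes must be a positive integer, got {self.pulse_minutes!r}"
            )
        if self.modulator != "none" and self.cue == "none":
            raise DesignError("a modulator requires a cue (modulator != none with cue == none)")

    @property
    def condition(self) -> tuple[str, str, int]:
        """Condition key ``(cue, modulator, pulse_minutes)``."""
        return (self.cue, self.modulator, int(self.pulse_minutes))

    @property
    def sample_id(self) -> str:
        """Stable string identifier ``cue.modulator.pulse.replicate``."""
        return f"{self.cue}.{self.modulator}.{self.pulse_minutes}.{self.replicate_id}"

    @property
    def is_basal(self) -> bool:
        return self.cue == "none"


@dataclass(frozen=True)
class LabelTriplet:
    """One (protein, sample) cell: the three channel intensities plus ratios.

    Intensities are arbitrary MS intensity units, NaN when not detected.
    ``ratio_HM``/``ratio_ML`` are raw (not log) ratios, NaN whenever either
    parent channel is missing.  Ratio counts are the number of peptide ratio
    measurements behind each ratio (MaxQuant "Ratio count"); downstream
    filtering requires a minimum ratio count of 2.
    """

    intensity_L: float = math.nan
    intensity_M: float = math.nan
    intensity_H: float = math.nan
    ratio_HM: float = math.nan
    ratio_ML: float = math.nan
    ratio_count_HM: int = 0
    ratio_count_ML: int = 0

    def __post_init__(self) -> None:
        for name in ("intensity_L", "intensity_M", "intensity_H"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise IntegrityError(f"{name} must be >= 0, got {v}")
        for name in ("ratio_HM", "ratio_ML"):
            v = getattr(self, name)
            if not math.isnan(v) and v <= 0:
                raise IntegrityError(f"{name} must be positive, got {v}")
        for name in ("ratio_count_HM", "ratio_count_ML"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise IntegrityError(f"{name} must be an integer >= 0, got {v}")


class QuantMatrix:
    """Proteins x samples grid of L/M/H intensities, ratios and ratio counts.

    Internally stores one wide ``DataFrame`` per numeric field
    (index = protein IDs, columns = sample IDs, NaN = missing), plus an
    optional per-protein relative abundance of the pre-existing light
    protein (an iBAQ-like quantity supplied externally, never computed here).
    """

    def __init__(
        self,
        samples: Sequence[SampleInfo],
        fields: dict[str, pd.DataFrame],
        abundance: pd.Series | None = None,
    ):
        sample_ids = [s.sample_id for s in samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise DesignError("duplicate sample_id in design (replicate_id not unique)")
        missing = set(_FIELDS) - set(fields)
        if missing:
            raise IntegrityError(f"QuantMatrix missing fields: {sorted(missing)}")
        ref = fields[_FIELDS[0]]
        if not ref.index.is_unique:
            dup = ref.index[ref.index.duplicated()][0]
            raise IntegrityError(f"duplicate protein ID: {dup!r}")
        for name, df in fields.items():
            if list(df.columns) != sample_ids:
                raise DesignError(
                    f"field {name}: columns {list(df.columns)} do not match design "
                    f"sample ids {sample_ids}"
                )
            if not df.index.equals(ref.index):
                raise IntegrityError(f"field {name}: protein index mismatch")
        self.samples = list(samples)
        self._fields = {k: fields[k].astype(float) for k in _FIELDS}
        self._enforce_ratio_parentage()
        if abundance is not None:
            abundance = abundance.reindex(ref.index).astype(float)
            if (abundance.dropna() < 0).any():
                raise IntegrityError("abundance values must be >= 0")
        self.abundance = abundance

    def _enforce_ratio_parentage(self) -> None:
        # a ratio is missing whenever either parent channel is absent
        f = self._fields
        f["ratio_HM"] = f["ratio_HM"].where(
            f["intensity_H"].notna() & f["intensity_M"].notna()
        )
        f["ratio_ML"] = f["ratio_ML"].where(
            f["intensity_M"].notna() & f["intensity_L"].notna()
        )

    # -- accessors ---------------------------------------------------------

    @property
    def protein_ids(self) -> pd.Index:
        return self._fields["intensity_L"].index

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def field(self, name: str) -> pd.DataFrame:
        """Wide proteins x samples table for one field (a copy-safe view)."""
        return self._fields[name]

    def intensity(self, channel: str) -> pd.DataFrame:
        if channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        return self._fields[f"intensity_{channel}"]

    def sample(self, sample_id: str) -> SampleInfo:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def cell(self, protein_id: str, sample_id: str) -> LabelTriplet:
        """The :class:`LabelTriplet` at one (protein, sample) address."""
        vals = {}
        for name in _FIELDS:
            v = self._fields[name].at[protein_id, sample_id]
            if name.startswith("ratio_count"):
                vals[name] = 0 if pd.isna(v) else int(v)
            else:
                vals[name] = float(v) if pd.notna(v) else math.nan
        return LabelTriplet(**vals)

    def select_samples(self, predicate) -> "QuantMatrix":
        """Sub-matrix restricted to samples for which ``predicate(SampleInfo)``."""
        keep = [s for s in self.samples if predicate(s)]
        ids = [s.sample_id for s in keep]
        fields = {k: df[ids] for k, df in self._fields.items()}
        return QuantMatrix(keep, fields, self.abundance)

    def conditions(self) -> list[tuple[str, str, int]]:
        """Distinct condition keys in design order."""
        seen: list[tuple[str, str, int]] = []
        for s in self.samples:
            if s.condition not in seen:
                seen.append(s.condition)
        return seen

    # -- serialization -----------------------------------------------------

    def to_long(self) -> pd.DataFrame:
        """Long-format table: one row per detected (protein, sample, channel).

        Ratio columns follow the channel convention of the long-format
        dialect: the H row carries the H/M ratio and its count, the M row
        carries M/L, the L row carries neither.
        """
        rows = []
        for ch in CHANNELS:
            inten = self._fields[f"intensity_{ch}"]
            stacked = inten.stack(future_stack=True).rename("intensity").reset_index()
            stacked.columns = ["protein_id", "sample_id", "intensity"]
            stacked["channel"] = ch
            if ch == "H":
                r = self._fields["ratio_HM"].stack(future_stack=True)
                c = self._fields["ratio_count_HM"].stack(future_stack=True)
            elif ch == "M":
                r = self._fields["ratio_ML"].stack(future_stack=True)
                c = self._fields["ratio_count_ML"].stack(future_stack=True)
            else:
                r = c = None
            if r is not None:
                key = pd.MultiIndex.from_frame(stacked[["protein_id", "sample_id"]])
                stacked["ratio"] = r.reindex(key).to_numpy()
                stacked["ratio_count"] = c.reindex(key).to_numpy()
            else:
                stacked["ratio"] = np.nan
                stacked["ratio_count"] = np.nan
            rows.append(stacked)
        out = pd.concat(rows, ignore_index=True)
        out = out[out["intensity"].notna()].reset_index(drop=True)
        return out[["protein_id", "sample_id", "channel", "intensity", "ratio", "ratio_count"]]

    def equals(self, other: "QuantMatrix") -> bool:
        if self.sample_ids != other.sample_ids:
            return False
        if not self.protein_ids.sort_values().equals(other.protein_ids.sort_values()):
            return False
        order = self.protein_ids.sort_values()
        for name in _FIELDS:
            a = self._fields[name].reindex(order)
            b = other._fields[name].reindex(order)
            if not np.allclose(a.to_numpy(), b.to_numpy(), rtol=1e-9, atol=0, equal_nan=True):
                return False
        return True


# ---------------------------------------------------------------------------
# Design table
# ---------------------------------------------------------------------------


def parse_design(path: str | Path) -> list[SampleInfo]:
    """Read a tab-separated sample-design table.

    Required columns: ``cue``, ``modulator``, ``pulse_minutes``,
    ``replicate_id``.  Unknown cue/modulator strings and non-positive pulse
    durations raise :class:`~pulseprot.errors.DesignError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["cue", "modulator", "pulse_minutes", "replicate_id"]
    for col in required:
        if col not in df.columns:
            raise DesignError(f"design table missing required column {col!r}")
    samples = []
    for _, row in df.iterrows():
        try:
            pulse = int(row["pulse_minutes"])
        except ValueError as exc:
            raise DesignError(f"non-integer pulse_minutes {row['pulse_minutes']!r}") from exc
        samples.append(
            SampleInfo(
                cue=str(row["cue"]),
                modulator=str(row["modulator"]),
                pulse_minutes=pulse,
                replicate_id=str(row["replicate_id"]),
            )
        )
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise DesignError("replicate_id not unique within a condition")
    return samples


def write_design(samples: Sequence[SampleInfo], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "cue": [s.cue for s in samples],
            "modulator": [s.modulator for s in samples],
            "pulse_minutes": [s.pulse_minutes for s in samples],
            "replicate_id": [s.replicate_id for s in samples],
        }
    )
    write_table(df, path)


# ---------------------------------------------------------------------------
# Quantification tables
# ---------------------------------------------------------------------------


def parse_quant_table(
    path: str | Path,
    dialect: str,
    design: Sequence[SampleInfo] | str | Path,
) -> QuantMatrix:
    """Parse a quantification table into a :class:`QuantMatrix`.

    Parameters
    ----------
    path : path
        Tab-separated input table.
    dialect : {"maxquant_proteingroups", "long_format"}
        ``maxquant_proteingroups`` expects per-sample columns named
        ``"Intensity L <sample_id>"``, ``"Ratio H/M <sample_id>"``,
        ``"Ratio H/M count <sample_id>"`` (and M/L analogues) plus
        ``"Protein IDs"``; rows flagged in ``Reverse`` or
        ``Potential contaminant`` are removed.  ``long_format`` expects
        columns ``protein_id, sample_id, channel, intensity, ratio,
        ratio_count`` with the H row carrying H/M and the M row carrying M/L,
        and is assumed decoy/contaminant free.
    design : list of SampleInfo or path
        The sample design; sample IDs must match the table's sample labels.

    Notes
    -----
    Zero intensities are mapped to missing (MS non-detection semantics).
    Rows with low ratio counts are *retained* here and flagged for the
    downstream minimum-ratio-count filter.
    """
    if not isinstance(design, (list, tuple)):
        design = parse_design(design)
    if dialect == "maxquant_proteingroups":
        return _parse_maxquant(path, design)
    if dialect == "long_format":
        return _parse_long(path, design)
    raise ValueError(f"unknown dialect {dialect!r}")


_MQ_FIELD_COLUMNS = {
    "intensity_L": "Intensity L {sid}",
    "intensity_M": "Intensity M {sid}",
    "intensity_H": "Intensity H {sid}",
    "ratio_HM": "Ratio H/M {sid}",
    "ratio_ML": "Ratio M/L {sid}",
    "ratio_count_HM": "Ratio H/M count {sid}",
    "ratio_count_ML": "Ratio M/L count {sid}",
}


def _parse_maxquant(path: str | Path, design: Sequence[SampleInfo]) -> QuantMatrix:
    df = pd.read_csv(path, sep="\t")
    if "Protein IDs" not in df.columns:
        raise FormatError("maxquant table missing required column 'Protein IDs'")
    # drop reverse decoys and contaminants ('+' flags, MaxQuant convention)
    for flag in ("Reverse", "Potential contaminant", "Contaminant"):
        if flag in df.columns:
            df = df[df[flag].fillna("") != "+"]
    df = df.set_index("Protein IDs")
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()][0]
        raise IntegrityError(f"duplicate protein ID: {dup!r}")
    fields = {}
    sample_ids = [s.sample_id for s in design]
    for fname, template in _MQ_FIELD_COLUMNS.items():
        cols = {}
        for sid in sample_ids:
            col = template.format(sid=sid)
            if col not in df.columns:
                raise FormatError(f"maxquant table missing required column {col!r}")
            cols[sid] = pd.to_numeric(df[col], errors="coerce")
        block = pd.DataFrame(cols)
        if fname.startswith("intensity"):
            block = block.replace(0.0, np.nan)
        elif fname.startswith("ratio_count"):
            block = block.fillna(0.0)
        else:
            block = block.replace(0.0, np.nan)
        fields[fname] = block
    abundance = None
    if "iBAQ L" in df.columns:
        abundance = pd.to_numeric(df["iBAQ L"], errors="coerce").replace(0.0, np.nan)
    return QuantMatrix(design, fields, abundance)


def _parse_long(path: str | Path, design: Sequence[SampleInfo]) -> QuantMatrix:
    df = pd.read_csv(path, sep="\t")
    required = ["protein_id", "sample_id", "channel", "intensity", "ratio", "ratio_count"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"long-format table missing required column {col!r}")
    bad = set(df["channel"]) - set(CHANNELS)
    if bad:
        raise FormatError(f"unknown channel labels {sorted(bad)}; expected {CHANNELS}")
    sample_ids = [s.sample_id for s in design]
    unknown = set(df["sample_id"]) - set(sample_ids)
    if unknown:
        raise DesignError(
            f"table sample ids {sorted(unknown)} not present in the design"
        )
    dupes = df.duplicated(subset=["protein_id", "sample_id", "channel"])
    if dupes.any():
        row = df[dupes].iloc[0]
        raise IntegrityError(
            f"duplicate (protein, sample, channel) entry: "
            f"({row['protein_id']!r}, {row['sample_id']!r}, {row['channel']!r})"
        )
    proteins = pd.Index(pd.unique(df["protein_id"]), name="protein_id")

    def pivot(sub: pd.DataFrame, value: str) -> pd.DataFrame:
        wide = sub.pivot(index="protein_id", columns="sample_id", values=value)
        return wide.reindex(index=proteins, columns=sample_ids)

    fields = {}
    for ch in CHANNELS:
        sub = df[df["channel"] == ch]
        inten = pivot(sub, "intensity").replace(0.0, np.nan)
        fields[f"intensity_{ch}"] = inten
        if ch == "H":
            fields["ratio_HM"] = pivot(sub, "ratio").replace(0.0, np.nan)
            fields["ratio_count_HM"] = pivot(sub, "ratio_count").fillna(0.0)
        elif ch == "M":
            fields["ratio_ML"] = pivot(sub, "ratio").replace(0.0, np.nan)
            fields["ratio_count_ML"] = pivot(sub, "ratio_count").fillna(0.0)
    abundance = None
    if "abundance" in df.columns:
        ab = df.drop_duplicates("protein_id").set_index("protein_id")["abundance"]
        abundance = pd.to_numeric(ab, errors="coerce").reindex(proteins)
    return QuantMatrix(list(design), fields, abundance)


def write_quant_long(quant: QuantMatrix, path: str | Path) -> None:
    """Write a QuantMatrix in the long-format dialect (round-trip safe)."""
    long = quant.to_long()
    if quant.abundance is not None:
        long = long.merge(
            quant.abundance.rename("abundance"),
            left_on="protein_id",
            right_index=True,
            how="left",
        )
    write_table(long, path)


def write_table(result: pd.DataFrame, path: str | Path) -> None:
    """Write any flat tabular result as TSV.

    Floats are rendered with 12 significant digits so that reading the file
    back reproduces the values; UTF-8, '.' decimal separator, header always
    present (an empty result yields a header-only file).
    """
    if not isinstance(result, pd.DataFrame):
        result = pd.DataFrame(result)
    try:
        result.to_csv(path, sep="\t", index=False, float_format="%.12g", encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write table to {path}: {exc}") from exc
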