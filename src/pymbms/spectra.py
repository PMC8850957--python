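"""Data model, I/O and normalization for unit-mass py-MBMS spectra.

A pyrolysis molecular-beam mass spectrum is recorded here as a vector of
ion-count intensities on integer m/z channels 30..450 (421 channels).
Spectra are normalized either to unit total ion current (TIC) or to unit
mean channel intensity before any downstream scoring or modeling, and
analytical replicates of the same biomass sample are averaged after
normalization so that run-to-run differences in total pyrolyzate yield do
not weight one replicate over another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InconsistentNormalizationError,
    InvalidSpectrumError,
    ParseError,
)

MZ_MIN = 30
MZ_MAX = 450
N_CHANNELS = MZ_MAX - MZ_MIN + 1  # 421
MZ_CHANNELS = np.arange(MZ_MIN, MZ_MAX + 1)

RAW = "raw"
MEAN = "mean"
TIC = "tic"
_NORM_STATES = (RAW, MEAN, TIC)


def mz_index(mz: int) -> int:
    """Channel index of an integer m/z value."""
    if not (MZ_MIN <= mz <= MZ_MAX):
        raise ValueError(f"m/z {mz} outside channel range [{MZ_MIN}, {MZ_MAX}]")
    return int(mz) - MZ_MIN


@dataclass(frozen=True)
class MassSpectrum:
    """One analytical replicate's intensity vector over m/z 30..450."""

    sample_id: str
    replicate_id: str
    intensities: np.ndarray
    normalization_state: str = RAW

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        if arr.shape != (N_CHANNELS,):
            raise InvalidSpectrumError(
                f"spectrum {self.sample_id}/{self.replicate_id}: expected "
                f"{N_CHANNELS} channels, got shape {arr.shape}"
            )
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise InvalidSpectrumError(
                f"spectrum {self.sample_id}/{self.replicate_id}: intensities "
                "must be finite and non-negative"
            )
        if self.normalization_state not in _NORM_STATES:
            raise InvalidSpectrumError(
                f"unknown normalization state {self.normalization_state!r}"
            )
        object.__setattr__(self, "intensities", arr)

    def intensity_at(self, mz: int) -> float:
        return float(self.intensities[mz_index(mz)])


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample provenance: genotype, pedigree parents, field position."""

    sample_id: str
    genotype_id: str = ""
    population: str = "natural"  # "natural" or "pedigree"
    mother_id: str | None = None
    father_id: str | None = None
    field_row: int | None = None
    field_col: int | None = None
    n_replicates: int = 1

    def __post_init__(self):
        if self.population == "pedigree" and (
            self.mother_id is None or self.father_id is None
        ):
            raise ValueError(
                f"pedigree sample {self.sample_id} must carry mother_id and father_id"
            )


@dataclass
class SpectrumMatrix:
    """Samples x 421 channels, one row per sample after replicate averaging."""

    sample_ids: list[str]
    matrix: np.ndarray
    normalization_state: str = RAW
    metadata: list[SampleMetadata] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != N_CHANNELS:
            raise ValueError(f"matrix must be n x {N_CHANNELS}")
        if self.matrix.shape[0] != len(self.sample_ids):
            raise ValueError("row count must equal sample_id count")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids in SpectrumMatrix")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, sample_id: str) -> np.ndarray:
        return self.matrix[self.sample_ids.index(sample_id)]

    def to_spectra(self) -> list[MassSpectrum]:
        return [
            MassSpectrum(sid, "mean", self.matrix[i], self.normalization_state)
            for i, sid in enumerate(self.sample_ids)
        ]


def tic_normalize(s: MassSpectrum) -> MassSpectrum:
    """Scale so channel intensities sum to one (unit total ion current)."""
    total = s.intensities.sum()
    if total <= 0:
        raise InvalidSpectrumError(
            f"spectrum {s.sample_id}/{s.replicate_id}: all-zero, cannot TIC-normalize"
        )
    return replace(s, intensities=s.intensities / total, normalization_state=TIC)


def mean_normalize(s: MassSpectrum) -> MassSpectrum:
    """Scale so the mean intensity over the 421 channels equals one."""
    m = s.intensities.mean()
    if m <= 0:
        raise InvalidSpectrumError(
            f"spectrum {s.sample_id}/{s.replicate_id}: all-zero, cannot mean-normalize"
        )
    return replace(s, intensities=s.intensities / m, normalization_state=MEAN)


def normalize(s: MassSpectrum, state: str) -> MassSpectrum:
    if state == TIC:
        return tic_normalize(s)
    if state == MEAN:
        return mean_normalize(s)
    if state == RAW:
        return s
    raise ValueError(f"unknown normalization state {state!r}")


def average_replicates(
    spectra: Iterable[MassSpectrum],
    metadata: Sequence[SampleMetadata] | None = None,
) -> SpectrumMatrix:
    """Channel-wise arithmetic mean of each sample's replicates.

    All input spectra must share one normalization state; replicates should
    be normalized individually *before* averaging so unequal total pyrolyzate
    yields between duplicate runs carry equal weight.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to average")
    states = {s.normalization_state for s in spectra}
    if len(states) > 1:
        raise InconsistentNormalizationError(
            f"mixed normalization states {sorted(states)} in replicate averaging"
        )
    by_sample: dict[str, list[MassSpectrum]] = {}
    for s in spectra:
        by_sample.setdefault(s.sample_id, []).append(s)

    meta_by_id = {m.sample_id: m for m in metadata} if metadata else {}
    sample_ids = list(by_sample)
    rows = np.vstack(
        [np.mean([s.intensities for s in by_sample[sid]], axis=0) for sid in sample_ids]
    )
    out_meta = []
    for sid in sample_ids:
        base = meta_by_id.get(sid, SampleMetadata(sample_id=sid, genotype_id=sid))
        out_meta.append(replace(base, n_replicates=len(by_sample[sid])))
    return SpectrumMatrix(sample_ids, rows, states.pop(), out_meta)


# ---------------------------------------------------------------------------
# Delimited-text I/O
#
# Spectra file: one row per replicate, columns sample_id, replicate_id,
# mz_30 .. mz_450. Metadata file: sample_id, genotype_id, population,
# mother_id, father_id, field_row, field_col.
# ---------------------------------------------------------------------------

_MZ_COLUMNS = [f"mz_{mz}" for mz in MZ_CHANNELS]


def read_spectra(path, dialect: str = "csv") -> list[MassSpectrum]:
    """Read replicate spectra from a delimited-text file.

    Rejects missing channels, fractional m/z column names, negative
    intensities and duplicate (sample_id, replicate_id) pairs, naming the
    offending row or column.
    """
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "replicate_id": str},
                     float_precision="round_trip")
    for col in df.columns:
        if col.startswith("mz_"):
            tail = col[3:]
            if not tail.isdigit():
                raise ParseError(f"fractional or malformed m/z column {col!r}")
    missing = [c for c in _MZ_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing m/z columns: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    seen: set[tuple[str, str]] = set()
    spectra = []
    for idx, rec in df.iterrows():
        key = (rec["sample_id"], rec["replicate_id"])
        if key in seen:
            raise ParseError(f"row {idx}: duplicate (sample_id, replicate_id) {key}")
        seen.add(key)
        vals = rec[_MZ_COLUMNS].to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ParseError(f"row {idx} (sample {key[0]}): negative intensity")
        state = str(rec["normalization_state"]) if "normalization_state" in df.columns else RAW
        spectra.append(MassSpectrum(key[0], key[1], vals, state))
    return spectra


def write_spectra(spectra: Iterable[MassSpectrum], path, dialect: str = "csv") -> None:
    """Write replicate spectra; round-trips intensities to full precision."""
    sep = "\t" if dialect == "tsv" else ","
    spectra = list(spectra)
    df = pd.DataFrame(
        np.vstack([s.intensities for s in spectra]), columns=_MZ_COLUMNS
    )
    df.insert(0, "normalization_state", [s.normalization_state for s in spectra])
    df.insert(0, "replicate_id", [s.replicate_id for s in spectra])
    df.insert(0, "sample_id", [s.sample_id for s in spectra])
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_metadata(path) -> list[SampleMetadata]:
    df = pd.read_csv(path, dtype=str)
    out = []
    for idx, rec in df.iterrows():
        def _opt(key):
            v = rec.get(key)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) or v == "" else v

        fr, fc = _opt("field_row"), _opt("field_col")
        try:
            out.append(
                SampleMetadata(
                    sample_id=rec["sample_id"],
                    genotype_id=rec.get("genotype_id", rec["sample_id"]),
                    population=rec.get("population", "natural"),
                    mother_id=_opt("mother_id"),
                    father_id=_opt("father_id"),
                    field_row=int(fr) if fr is not None else None,
                    field_col=int(fc) if fc is not None else None,
                    n_replicates=int(_opt("n_replicates") or 1),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ParseError(f"metadata row {idx}: {exc}") from exc
    return out


def write_metadata(metadata: Iterable[SampleMetadata], path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "genotype_id": m.genotype_id,
            "population": m.population,
            "mother_id": m.mother_id or "",
            "father_id": m.father_id or "",
            "field_row": "" if m.field_row is None else m.field_row,
            "field_col": "" if m.field_col is None else m.field_col,
            "n_replicates": m.n_replicates,
        }
        for m in metadata
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
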