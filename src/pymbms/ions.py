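"""Reduced-ion estimators: lignin content, S/G ratio, single-point sugars.

Lignin content is scored by summing a fixed set of lignin-derived marker
ions and scaling against a reference standard of known Klason lignin
content. The monolignol syringyl/guaiacyl (S/G) ratio divides the summed
syringyl-ion intensity by the summed guaiacyl-ion intensity. C6 (glucose)
and C5 (xylose) sugar contents can likewise be estimated by a single-point
response-factor comparison of summed sugar-derived ions against a standard
of known composition — a fast method that trades accuracy for throughput.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .errors import InvalidStandardError, UndefinedRatioError
from .spectra import MZ_MAX, MZ_MIN, MassSpectrum, SpectrumMatrix, mz_index

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IonSet:
    """Named list of diagnostic m/z channels, optionally sublabelled S/G."""

    name: str
    members: tuple[int, ...]
    sublabels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        members = tuple(int(m) for m in self.members)
        if len(set(members)) != len(members):
            raise ValueError(f"ion set {self.name!r}: duplicate members")
        for m in members:
            if not (MZ_MIN <= m <= MZ_MAX):
                raise ValueError(
                    f"ion set {self.name!r}: m/z {m} outside [{MZ_MIN}, {MZ_MAX}]"
                )
        for m, lab in self.sublabels.items():
            if m not in members:
                raise ValueError(f"ion set {self.name!r}: sublabel on non-member {m}")
            if lab not in ("S", "G"):
                raise ValueError(f"ion set {self.name!r}: sublabel {lab!r} not in {{S, G}}")
        object.__setattr__(self, "members", members)

    def sublabel_members(self, label: str) -> tuple[int, ...]:
        return tuple(m for m in self.members if self.sublabels.get(m) == label)


def load_ion_sets(path=None) -> dict[str, IonSet]:
    """Load ion sets from a YAML config; defaults to the shipped version."""
    if path is None:
        text = resources.files("pymbms.data").joinpath("ion_sets.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out = {}
    for name, spec in raw["sets"].items():
        out[name] = IonSet(
            name=name,
            members=tuple(spec["members"]),
            sublabels={int(k): v for k, v in spec.get("sublabels", {}).items()},
        )
    return out


_SHIPPED = load_ion_sets()
LIGNIN_IONS: IonSet = _SHIPPED["lignin"]
C6_IONS: IonSet = _SHIPPED["c6"]
C5_IONS: IonSet = _SHIPPED["c5"]


@dataclass(frozen=True)
class ReferenceStandard:
    """Sample of known composition used for single-point scaling."""

    spectrum: MassSpectrum
    known_value: float  # DW% for lignin, mg/mg or DW% for sugars
    target: str  # lignin | glucose | xylose

    def __post_init__(self):
        if self.known_value <= 0:
            raise ValueError("reference standard known_value must be positive")


@dataclass
class CompositionEstimate:
    sample_id: str
    glucose_dw_pct: float | None = None
    xylose_dw_pct: float | None = None
    lignin_pct: float | None = None
    sg_ratio: float | None = None
    method: str = "single_point"


def ion_sum(s: MassSpectrum, ions: IonSet) -> float:
    """Sum of intensities at the set's member channels (0 for empty set)."""
    if not ions.members:
        return 0.0
    idx = [mz_index(m) for m in ions.members]
    return float(s.intensities[idx].sum())


def sg_ratio(s: MassSpectrum, lignin: IonSet = LIGNIN_IONS) -> float:
    """Syringyl/guaiacyl ratio: sum of S ions over sum of G ions."""
    s_sum = sum(s.intensity_at(m) for m in lignin.sublabel_members("S"))
    g_sum = sum(s.intensity_at(m) for m in lignin.sublabel_members("G"))
    if g_sum <= 0:
        raise UndefinedRatioError(
            f"sample {s.sample_id}: guaiacyl ion sum is zero, S/G undefined"
        )
    return s_sum / g_sum


def single_point_estimate(
    s: MassSpectrum, std: ReferenceStandard, ions: IonSet
) -> float:
    """Response-factor estimate: known value scaled by the ion-sum ratio."""
    if s.normalization_state != std.spectrum.normalization_state:
        raise InvalidStandardError(
            "sample and standard must share a normalization state "
            f"({s.normalization_state} vs {std.spectrum.normalization_state})"
        )
    denom = ion_sum(std.spectrum, ions)
    if denom <= 0:
        raise InvalidStandardError(
            f"standard for {std.target} has zero ion sum over set {ions.name!r}"
        )
    return std.known_value * ion_sum(s, ions) / denom


_TARGET_SETS = {"lignin": "lignin", "glucose": "c6", "xylose": "c5"}


def score_set(
    matrix: SpectrumMatrix,
    standards: dict[str, ReferenceStandard] | None = None,
    ion_sets: dict[str, IonSet] | None = None,
    compute_sg: bool = True,
) -> list[CompositionEstimate]:
    """Batch single-point scoring of a spectrum matrix.

    Computes whichever targets have a standard supplied, plus the S/G ratio.
    A sample whose S/G is undefined gets a missing value and a warning, not
    a crash.
    """
    standards = standards or {}
    sets = ion_sets or _SHIPPED
    estimates = []
    for spec in matrix.to_spectra():
        est = CompositionEstimate(sample_id=spec.sample_id, method="single_point")
        for target, std in standards.items():
            val = single_point_estimate(spec, std, sets[_TARGET_SETS[target]])
            setattr(est, {"lignin": "lignin_pct", "glucose": "glucose_dw_pct",
                          "xylose": "xylose_dw_pct"}[target], val)
        if compute_sg:
            try:
                est.sg_ratio = sg_ratio(spec, sets["lignin"])
            except UndefinedRatioError:
                logger.warning("sample %s: S/G undefined (zero G sum)", spec.sample_id)
                est.sg_ratio = None
        estimates.append(est)
    return estimates


def summarize(values) -> dict[str, float]:
    """Mean/max/min/range/SD summary used for population reporting."""
    arr = np.asarray([v for v in values if v is not None and math.isfinite(v)], float)
    return {
        "mean": float(arr.mean()),
        "max": float(arr.max()),
        "min": float(arr.min()),
        "range": float(arr.max() - arr.min()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
    }
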