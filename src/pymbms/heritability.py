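"""Broad-sense heritability with thin-plate-spline microspatial correction.

Clonally replicated field trials let total genotypic variance be estimated
directly: every ramet (clonal copy) of a genotype shares its genotype, so
the between-genotype variance component of a one-way random-effects model
is sigma2_G and the within-genotype component is sigma2_E, giving broad-sense
heritability H2 = sigma2_G / (sigma2_G + sigma2_E).

Field trials carry smooth microspatial trends (soil, moisture, edge
effects) that inflate the within-genotype variance when ramets are spread
across the grid. Before estimating variance components, phenotypes are
corrected by fitting a thin-plate regression spline f(row, col) to the
values, subtracting it, and re-adding the grand mean. Smoothing is chosen
by generalized cross-validation (GCV) so that spatially unstructured data
are left essentially untouched.

The spline is low-rank: radial basis functions phi(r) = r^2 log r at up to
``max_knots`` thinned knot locations plus a linear polynomial, with the
radial coefficients constrained orthogonal to the polynomial at the knots
(the standard conditional-positivity constraint). The penalized solve is
O(n m^2 + m^3) for m knots, so large trials stay tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from .errors import DegenerateGeometryError, NonEstimableError

# ---------------------------------------------------------------------------
# Phenotype records
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeRecord:
    """One ramet's trait value with genotype and field position."""

    genotype_id: str
    value: float
    field_row: int | None = None
    field_col: int | None = None
    mother_id: str | None = None
    father_id: str | None = None
    ramet_id: str = ""


@dataclass
class SpatialCorrectionConfig:
    smoothing: Literal["gcv", "fixed"] = "gcv"
    lam: float | None = None  # required when smoothing == "fixed"
    max_knots: int = 200
    # log10 lambda grid searched under GCV
    lambda_grid: tuple[float, float, int] = (-8.0, 8.0, 33)

    def __post_init__(self):
        if self.smoothing == "fixed" and (self.lam is None or self.lam <= 0):
            raise ValueError("fixed smoothing requires lam > 0")


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    """phi(r) = r^2 log r, with phi(0) = 0."""
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = r[pos] ** 2 * np.log(r[pos])
    return out


def _thin_knots(coords: np.ndarray, max_knots: int) -> np.ndarray:
    """Deterministic knot thinning: even strides through lexsorted uniques."""
    uniq = np.unique(coords, axis=0)
    if len(uniq) <= max_knots:
        return uniq
    idx = np.linspace(0, len(uniq) - 1, max_knots).round().astype(int)
    return uniq[np.unique(idx)]


def fit_tps_surface(
    coords: np.ndarray, values: np.ndarray, config: SpatialCorrectionConfig
) -> tuple[np.ndarray, float, float]:
    """Fit the penalized thin-plate spline; return (fitted, lambda, edf)."""
    coords = np.asarray(coords, float)
    y = np.asarray(values, float)
    n = len(y)
    uniq = np.unique(coords, axis=0)
    if len(uniq) < 4:
        raise DegenerateGeometryError(
            f"only {len(uniq)} distinct field coordinates; spatial surface not identifiable"
        )
    # standardize coordinates for numerical conditioning
    scale = coords.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (coords - coords.mean(axis=0)) / scale
    knots = _thin_knots(Xs, config.max_knots)
    m = len(knots)

    dists = np.sqrt(((Xs[:, None, :] - knots[None, :, :]) ** 2).sum(-1))
    E = _tps_kernel(dists)  # n x m radial basis
    T = np.column_stack([np.ones(n), Xs])  # n x 3 polynomial
    Kd = np.sqrt(((knots[:, None, :] - knots[None, :, :]) ** 2).sum(-1))
    K = _tps_kernel(Kd)  # m x m penalty kernel
    Tk = np.column_stack([np.ones(m), knots])

    # constrain radial coefficients orthogonal to the polynomial at the knots
    _, _, Vt = np.linalg.svd(Tk.T, full_matrices=True)
    Z = Vt[3:].T  # m x (m-3) null space basis
    B = np.column_stack([E @ Z, T])
    S = np.zeros((B.shape[1], B.shape[1]))
    S[: m - 3, : m - 3] = Z.T @ K @ Z
    # symmetrize + tiny ridge: K is only conditionally PD, guard roundoff
    S = (S + S.T) / 2
    S[: m - 3, : m - 3] += 1e-10 * np.eye(m - 3) * max(np.trace(S), 1.0) / m

    BtB = B.T @ B
    Bty = B.T @ y
    # scale-free lambda: normalize penalty to the data-matrix scale
    s_scale = np.trace(BtB) / max(np.trace(S), 1e-300)

    def solve(lam):
        A = BtB + lam * s_scale * S
        beta = np.linalg.solve(A, Bty)
        fitted = B @ beta
        edf = float(np.trace(np.linalg.solve(A, BtB)))
        return fitted, edf

    if config.smoothing == "fixed":
        fitted, edf = solve(config.lam)
        return fitted, float(config.lam), edf

    lo, hi, npts = config.lambda_grid
    best = None
    for lam in np.logspace(lo, hi, npts):
        fitted, edf = solve(lam)
        rss = float(((y - fitted) ** 2).sum())
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, fitted, edf)
    _, lam, fitted, edf = best
    return fitted, float(lam), edf


def tps_correct(
    records: Sequence[PhenotypeRecord],
    config: SpatialCorrectionConfig | None = None,
) -> list[PhenotypeRecord]:
    """Remove the fitted smooth field surface; preserve the grand mean."""
    config = config or SpatialCorrectionConfig()
    records = list(records)
    if len(records) < 20:
        raise ValueError("spatial correction needs >= 20 records")
    if any(r.field_row is None or r.field_col is None for r in records):
        raise DegenerateGeometryError("all records need field coordinates")
    coords = np.array([[r.field_row, r.field_col] for r in records], float)
    y = np.array([r.value for r in records], float)
    if np.std(y) == 0:
        return [PhenotypeRecord(**{**r.__dict__}) for r in records]
    fitted, _, _ = fit_tps_surface(coords, y, config)
    corrected = y - fitted + y.mean()
    out = []
    for r, v in zip(records, corrected):
        d = dict(r.__dict__)
        d["value"] = float(v)
        out.append(PhenotypeRecord(**d))
    return out


# ---------------------------------------------------------------------------
# Variance components
# ---------------------------------------------------------------------------


@dataclass
class VarianceDecomposition:
    sigma2_G: float
    sigma2_E: float
    H2: float
    method: str
    ci_low: float | None = None
    ci_high: float | None = None
    trait: str = ""

    def __post_init__(self):
        assert 0.0 <= self.H2 <= 1.0


def _group(records: Sequence[PhenotypeRecord]):
    groups: dict[str, list[float]] = {}
    for r in records:
        groups.setdefault(r.genotype_id, []).append(r.value)
    return {g: np.asarray(v, float) for g, v in groups.items()}


def _moments(groups) -> tuple[float, float]:
    """One-way ANOVA expectations with the unbalanced-design coefficient n0."""
    k = len(groups)
    ni = np.array([len(v) for v in groups.values()], float)
    N = ni.sum()
    means = np.array([v.mean() for v in groups.values()])
    grand = sum(v.sum() for v in groups.values()) / N
    ss_between = float((ni * (means - grand) ** 2).sum())
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in groups.values()))
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k)
    n0 = (N - (ni**2).sum() / N) / (k - 1)
    sigma2_G = max(0.0, (ms_between - ms_within) / n0)
    return sigma2_G, ms_within


def _reml(groups) -> tuple[float, float]:
    """REML for the one-way random-effects model, direct closed-form likelihood."""
    ni = np.array([len(v) for v in groups.values()], float)
    means = np.array([v.mean() for v in groups.values()])
    ssw = np.array([((v - v.mean()) ** 2).sum() for v in groups.values()])

    def neg2_reml(params):
        log_sg, log_se = params
        sg, se = np.exp(log_sg), np.exp(log_se)
        di = se + ni * sg
        wi = ni / di
        mu = (wi * means).sum() / wi.sum()
        ll = (
            ((ni - 1) * np.log(se)).sum()
            + np.log(di).sum()
            + ssw.sum() / se
            + (wi * (means - mu) ** 2).sum()
            + np.log(wi.sum())
        )
        return ll

    sg0, se0 = _moments(groups)
    se0 = max(se0, 1e-8)
    sg0 = max(sg0, 1e-4 * se0)
    res = optimize.minimize(
        neg2_reml,
        x0=[np.log(sg0), np.log(se0)],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    sg, se = np.exp(res.x)
    # compare against the sigma2_G -> 0 boundary
    lo = optimize.minimize_scalar(
        lambda ls: neg2_reml([np.log(1e-12 * se0), ls]),
        bounds=(np.log(se0) - 10, np.log(se0) + 10),
        method="bounded",
    )
    if lo.fun < res.fun:
        sg, se = 0.0, float(np.exp(lo.x))
    return float(sg), float(se)


def estimate_H2(
    records: Sequence[PhenotypeRecord],
    method: Literal["moments", "reml"] = "moments",
    trait: str = "",
) -> VarianceDecomposition:
    """Broad-sense heritability from clonal replication.

    Genotype is a random group effect; the moments method uses one-way
    ANOVA expectations with the unbalanced coefficient
    n0 = (N - sum n_i^2 / N) / (k - 1) and truncates negative genotypic
    variance at zero; the REML method maximizes the restricted likelihood.
    """
    groups = _group(records)
    if len(groups) < 2:
        raise NonEstimableError("need >= 2 genotypes")
    ni = [len(v) for v in groups.values()]
    if max(ni) < 2:
        raise NonEstimableError("no clonal replication: all genotypes have one ramet")
    if method == "moments":
        sigma2_G, sigma2_E = _moments(groups)
    elif method == "reml":
        sigma2_G, sigma2_E = _reml(groups)
    else:
        raise ValueError(f"unknown method {method!r}")
    tot = sigma2_G + sigma2_E
    H2 = sigma2_G / tot if tot > 0 else 0.0
    H2 = min(max(H2, 0.0), 1.0)
    return VarianceDecomposition(
        sigma2_G=sigma2_G, sigma2_E=sigma2_E, H2=H2, method=method, trait=trait
    )


def bootstrap_ci(
    records: Sequence[PhenotypeRecord],
    method: str = "moments",
    n_boot: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for H2, resampling genotypes with replacement."""
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    groups = _group(records)
    gids = list(groups)
    if len(gids) < 10:
        import warnings

        warnings.warn("fewer than 10 genotypes: bootstrap CI unreliable")
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(n_boot):
        pick = rng.choice(len(gids), size=len(gids), replace=True)
        boot = []
        for j, gi in enumerate(pick):
            for v in groups[gids[gi]]:
                boot.append(PhenotypeRecord(genotype_id=f"b{j}", value=float(v)))
        try:
            vd = estimate_H2(boot, method=method)
        except NonEstimableError:
            continue
        if vd.sigma2_G + vd.sigma2_E == 0:
            continue  # zero-variance resample carries no information on H2
        stats.append(vd.H2)
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Pipeline: trait model -> spatial correction -> H2
# ---------------------------------------------------------------------------


@dataclass
class HeritabilityConfig:
    spatial: SpatialCorrectionConfig = field(default_factory=SpatialCorrectionConfig)
    apply_tps: bool = True
    method: Literal["moments", "reml"] = "moments"
    bootstrap: int = 0  # 0 disables the CI
    seed: int = 0
    per_ion: tuple[int, ...] = ()  # m/z channels for per-ion H2 (Table-style)


def heritability_pipeline(
    matrix,
    metadata,
    trait_models: dict,
    config: HeritabilityConfig | None = None,
) -> dict[str, VarianceDecomposition]:
    """Predict traits per ramet, spatially correct, and estimate H2.

    ``matrix`` is a SpectrumMatrix whose rows are ramets (sample_id = ramet),
    ``metadata`` maps sample ids to genotype and field position, and
    ``trait_models`` maps trait name to either a fitted PLSModel or a
    callable giving one value per row. Per-ion heritability is computed for
    any channels listed in ``config.per_ion``.
    """
    from .chemometrics import PLSModel, predict_pls
    from .spectra import mz_index

    config = config or HeritabilityConfig()
    meta_by_id = {m.sample_id: m for m in metadata}

    def records_for(values) -> list[PhenotypeRecord]:
        recs = []
        for sid, v in zip(matrix.sample_ids, values):
            m = meta_by_id[sid]
            recs.append(
                PhenotypeRecord(
                    genotype_id=m.genotype_id,
                    value=float(v),
                    field_row=m.field_row,
                    field_col=m.field_col,
                    mother_id=m.mother_id,
                    father_id=m.father_id,
                    ramet_id=sid,
                )
            )
        return recs

    jobs: dict[str, np.ndarray] = {}
    for trait, model in trait_models.items():
        if isinstance(model, PLSModel):
            jobs[trait] = predict_pls(model, matrix)
        else:
            jobs[trait] = np.asarray(model(matrix), float)
    for mz in config.per_ion:
        jobs[f"ion_{mz}"] = matrix.matrix[:, mz_index(mz)]

    results: dict[str, VarianceDecomposition] = {}
    for trait, values in jobs.items():
        recs = records_for(values)
        if config.apply_tps:
            recs = tps_correct(recs, config.spatial)
        vd = estimate_H2(recs, method=config.method, trait=trait)
        if config.bootstrap:
            vd.ci_low, vd.ci_high = bootstrap_ci(
                recs, method=config.method, n_boot=config.bootstrap, seed=config.seed
            )
        results[trait] = vd
    return results
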