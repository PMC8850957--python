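"""Synthetic py-MBMS study generator with known ground truth.

Real py-MBMS field campaigns pair thousands of spectra with reference
compositions measured by hydrolysis/NMR on a calibration subset. This
module emulates that statistical structure so the whole pipeline can be
exercised against latent truth:

* **Compositions** are drawn from a truncated multivariate normal over
  (glucose, xylose, lignin, S/G) whose defaults match the published
  population for *P. trichocarpa*: glucose 43-57 DW% (mean 48), xylose
  11-20 DW% (mean 17), lignin mean 24.6 SD 1.0, S/G mean 2.1 SD 0.1, with
  a strong negative glucose-xylose correlation (r = -0.76), a negative
  glucose-lignin correlation (r = -0.61) and a positive xylose-lignin
  correlation (r = +0.48).
* **Spectra** are linear mixtures of component basis patterns (C6 sugar,
  C5 sugar, S-lignin, G-lignin, broadband background) with multiplicative
  lognormal channel noise, then TIC-normalized. 80% of each component's
  ion yield sits on its annotated diagnostic ions and 20% on a shared
  low-mass background, so reduced-ion estimators are correlated with truth
  but biased by interference — single-point scoring underperforms a
  full-spectrum calibration, as observed within a single biomass type.
* **Reference measurements** add Gaussian error (default SD 0.01 mg/mg =
  1 DW%) to the latent sugar values, emulating hydrolysis/NMR error.
* **Pedigree trials** simulate a 7 x 7 factorial cross with clonally
  replicated genotypes on a field grid: genotype value = GCA(mother) +
  GCA(father) + SCA + within-family deviation, ramet phenotype = genotype
  value + smooth spatial surface + residual, with configurable broad-sense
  heritability (defaults 0.32 glucose, 0.34 xylose).

Everything is exactly reproducible from (seed, config); outputs carry a
provenance sidecar with the seed and a config hash.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .heritability import PhenotypeRecord
from .spectra import (
    MZ_CHANNELS,
    N_CHANNELS,
    MassSpectrum,
    SampleMetadata,
    mz_index,
    write_metadata,
    write_spectra,
)

TRAITS = ("glucose_dw_pct", "xylose_dw_pct", "lignin_pct", "sg_ratio")


@dataclass(frozen=True)
class CompositionTruth:
    """Latent per-sample composition (percent dry weight; S/G unitless)."""

    glucose_dw_pct: float
    xylose_dw_pct: float
    lignin_pct: float
    sg_ratio: float

    def __post_init__(self):
        if min(self.glucose_dw_pct, self.xylose_dw_pct, self.lignin_pct, self.sg_ratio) <= 0:
            raise ValueError("composition values must be positive")
        if self.glucose_dw_pct + self.xylose_dw_pct + self.lignin_pct >= 100:
            raise ValueError("glucose + xylose + lignin must stay below 100 DW%")


# Diagnostic-ion layouts for the component basis spectra. Weight order
# mirrors the observed correlation strength of each ion with its component.
_GLUCOSE_IONS = {126: 10, 98: 9, 69: 7, 70: 7, 84: 7, 57: 6, 60: 5, 73: 5, 144: 4, 96: 3}
_XYLOSE_IONS = {114: 8, 103: 5, 150: 5, 57: 4, 73: 4, 85: 3, 96: 3}
_S_LIGNIN_IONS = {154: 8, 167: 7, 168: 6, 182: 5, 194: 7, 208: 4, 210: 5, 152: 4, 180: 6}
_G_LIGNIN_IONS = {124: 8, 137: 7, 138: 6, 150: 5, 164: 5, 178: 5, 120: 4}


def _background_shape() -> np.ndarray:
    """Smooth low-mass-weighted broadband profile, unit sum."""
    shape = np.exp(-(MZ_CHANNELS - MZ_CHANNELS[0]) / 40.0)
    return shape / shape.sum()


def _basis(ions: dict[int, float], diagnostic_fraction: float = 0.8) -> np.ndarray:
    vec = np.zeros(N_CHANNELS)
    total = sum(ions.values())
    for mz, w in ions.items():
        vec[mz_index(mz)] = diagnostic_fraction * w / total
    vec += (1.0 - diagnostic_fraction) * _background_shape()
    return vec


def default_basis_spectra() -> dict[str, np.ndarray]:
    return {
        "glucose": _basis(_GLUCOSE_IONS),
        "xylose": _basis(_XYLOSE_IONS),
        "s_lignin": _basis(_S_LIGNIN_IONS),
        "g_lignin": _basis(_G_LIGNIN_IONS),
        "background": _background_shape(),
    }


@dataclass
class GeneratorConfig:
    """Composition, spectrum and reference-noise settings."""

    means: dict = field(
        default_factory=lambda: {
            "glucose_dw_pct": 48.0,
            "xylose_dw_pct": 17.0,
            "lignin_pct": 24.6,
            "sg_ratio": 2.1,
        }
    )
    # SDs for lignin and S/G are published; the sugar SDs place the
    # published ranges at roughly +/- 3 SD.
    sds: dict = field(
        default_factory=lambda: {
            "glucose_dw_pct": 2.3,
            "xylose_dw_pct": 1.5,
            "lignin_pct": 1.0,
            "sg_ratio": 0.1,
        }
    )
    ranges: dict = field(
        default_factory=lambda: {
            "glucose_dw_pct": (43.0, 57.0),
            "xylose_dw_pct": (11.0, 20.0),
            "lignin_pct": (19.3, 27.0),
            "sg_ratio": (1.4, 2.6),
        }
    )
    # order: glucose, xylose, lignin, sg
    correlations: list = field(
        default_factory=lambda: [
            [1.0, -0.76, -0.61, 0.0],
            [-0.76, 1.0, 0.48, 0.0],
            [-0.61, 0.48, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    spectral_noise_sd: float = 0.08  # lognormal sigma per channel
    reference_sd: dict = field(
        default_factory=lambda: {"glucose_dw_pct": 1.0, "xylose_dw_pct": 1.0}
    )  # 0.01 mg/mg = 1 DW%
    n_replicates: int = 2
    seed: int = 0

    def correlation_matrix(self) -> np.ndarray:
        C = np.asarray(self.correlations, float)
        if not np.allclose(C, C.T):
            raise ConfigError("correlation matrix must be symmetric")
        vals, vecs = np.linalg.eigh(C)
        if vals.min() < -1e-10:
            warnings.warn(
                "correlation matrix not positive semi-definite; repairing by "
                "eigenvalue clipping"
            )
            vals = np.clip(vals, 1e-8, None)
            C = vecs @ np.diag(vals) @ vecs.T
            d = np.sqrt(np.diag(C))
            C = C / np.outer(d, d)
        return C

    def validate(self):
        for t in TRAITS:
            lo, hi = self.ranges[t]
            if not (lo <= self.means[t] <= hi):
                raise ConfigError(f"range for {t} must contain its mean")
        return self


def config_hash(*configs) -> str:
    blob = json.dumps([asdict(c) for c in configs], sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def sample_compositions(
    n: int, config: GeneratorConfig | None = None, rng=None
) -> list[CompositionTruth]:
    """Draw compositions from the truncated correlated normal; seeded."""
    config = (config or GeneratorConfig()).validate()
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    mu = np.array([config.means[t] for t in TRAITS])
    sd = np.array([config.sds[t] for t in TRAITS])
    cov = config.correlation_matrix() * np.outer(sd, sd)
    lo = np.array([config.ranges[t][0] for t in TRAITS])
    hi = np.array([config.ranges[t][1] for t in TRAITS])

    if np.all(sd == 0):
        return [CompositionTruth(*mu) for _ in range(n)]

    out: list[CompositionTruth] = []
    drawn = accepted = 0
    while len(out) < n:
        batch = rng.multivariate_normal(mu, cov, size=max(n, 256), method="cholesky")
        keep = np.all((batch >= lo) & (batch <= hi), axis=1)
        drawn += len(batch)
        accepted += int(keep.sum())
        for row in batch[keep]:
            if len(out) < n:
                out.append(CompositionTruth(*row))
        if drawn >= 20000 and accepted / drawn < 0.01:
            raise ConfigError(
                f"rejection acceptance {accepted / drawn:.2%} < 1%: "
                "range/SD combination infeasible"
            )
    return out


def mix_components(
    abundances: dict[str, float],
    config: GeneratorConfig | None = None,
    rng=None,
    sample_id: str = "synthetic",
    replicate_id: str = "1",
    basis: dict[str, np.ndarray] | None = None,
) -> MassSpectrum:
    """Linear mixture of component basis spectra with lognormal channel
    noise, TIC-normalized. Scaling all abundances by a constant leaves the
    zero-noise output unchanged."""
    config = config or GeneratorConfig()
    basis = basis or default_basis_spectra()
    for name, vec in basis.items():
        if np.asarray(vec).shape != (N_CHANNELS,):
            raise ConfigError(f"basis {name!r} must have {N_CHANNELS} channels")
    unknown = set(abundances) - set(basis)
    if unknown:
        raise ConfigError(f"abundances for unknown components {sorted(unknown)}")
    spectrum = np.zeros(N_CHANNELS)
    for name, a in abundances.items():
        spectrum = spectrum + a * np.asarray(basis[name], float)
    if config.spectral_noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        sigma = config.spectral_noise_sd
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=N_CHANNELS)
        spectrum = spectrum * noise
    total = spectrum.sum()
    if total <= 0:
        raise ConfigError("mixture has zero total intensity")
    return MassSpectrum(sample_id, replicate_id, spectrum / total,
                        normalization_state="tic")


def _sg_split(truth: CompositionTruth, basis: dict[str, np.ndarray]) -> tuple[float, float]:
    """Split lignin mass into S and G monomer pools so the labeled-ion
    intensity ratio of the noise-free spectrum equals the latent S/G.

    The S/G ratio is operationally defined on the intensity scale (summed
    syringyl ions over summed guaiacyl ions), so the generator anchors its
    latent value to that scale, accounting for response-factor differences
    between the S and G basis patterns and for interference from sugar and
    background mass at the labeled channels.
    """
    from .ions import LIGNIN_IONS

    s_idx = [mz_index(m) for m in LIGNIN_IONS.sublabel_members("S")]
    g_idx = [mz_index(m) for m in LIGNIN_IONS.sublabel_members("G")]
    r = truth.sg_ratio
    L = truth.lignin_pct
    a_ss = basis["s_lignin"][s_idx].sum()
    a_sg = basis["s_lignin"][g_idx].sum()
    a_gs = basis["g_lignin"][s_idx].sum()
    a_gg = basis["g_lignin"][g_idx].sum()
    residual = 100.0 - truth.glucose_dw_pct - truth.xylose_dw_pct - L
    others = (
        truth.glucose_dw_pct * basis["glucose"]
        + truth.xylose_dw_pct * basis["xylose"]
        + residual * basis["background"]
    )
    c_s = others[s_idx].sum()
    c_g = others[g_idx].sum()
    denom = a_ss - r * a_sg - a_gs + r * a_gg
    lig_s = (r * c_g - c_s + (r * a_gg - a_gs) * L) / denom
    lig_s = float(np.clip(lig_s, 0.0, L))
    return lig_s, L - lig_s


def compose_spectrum(
    truth: CompositionTruth,
    config: GeneratorConfig | None = None,
    rng=None,
    sample_id: str = "synthetic",
    replicate_id: str = "1",
    basis: dict[str, np.ndarray] | None = None,
) -> MassSpectrum:
    """Compose one replicate spectrum from a latent composition.

    Component abundances are the DW% masses: glucose drives the C6 basis,
    xylose the C5 basis, lignin splits into S and G monomer pools such that
    the noise-free syringyl/guaiacyl intensity ratio equals the latent S/G,
    and the residual (non-sugar, non-lignin) mass drives the broadband
    background.
    """
    basis = basis or default_basis_spectra()
    for name, vec in basis.items():
        if np.asarray(vec).shape != (N_CHANNELS,):
            raise ConfigError(f"basis {name!r} must have {N_CHANNELS} channels")
    lig_s, lig_g = _sg_split(truth, basis)
    residual = 100.0 - truth.glucose_dw_pct - truth.xylose_dw_pct - truth.lignin_pct
    return mix_components(
        {
            "glucose": truth.glucose_dw_pct,
            "xylose": truth.xylose_dw_pct,
            "s_lignin": lig_s,
            "g_lignin": lig_g,
            "background": residual,
        },
        config=config,
        rng=rng,
        sample_id=sample_id,
        replicate_id=replicate_id,
        basis=basis,
    )


def nmr_measure(
    truths: list[CompositionTruth], config: GeneratorConfig | None = None, rng=None
) -> pd.DataFrame:
    """Reference-style sugar measurements: truth plus Gaussian error."""
    config = config or GeneratorConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rows = []
    for t in truths:
        row = {}
        for trait in ("glucose_dw_pct", "xylose_dw_pct"):
            sd = config.reference_sd.get(trait, 0.0)
            val = getattr(t, trait)
            row[trait] = val + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pedigree field trials
# ---------------------------------------------------------------------------


@dataclass
class PedigreeSimConfig:
    """7 x 7 factorial cross with clonal replication on a field grid.

    Variance components are on a standard trait scale with total
    phenotypic variance sigma2_G + sigma2_E = 1; the genotypic variance
    splits into parental main effects (GCA), cross interaction (SCA) and
    within-family deviation. Default splits match published broad-sense
    heritabilities: glucose H2 = 0.32, xylose H2 = 0.34.
    """

    n_mothers: int = 7
    n_fathers: int = 7
    progeny_per_family: int = 10
    ramets_per_genotype: int = 5
    sigma2_G: float = 0.32  # glucose default; use 0.34 for xylose
    sigma2_E: float = 0.68
    # fractions of sigma2_G assigned to each genetic component
    gca_fraction: float = 0.25  # per parent
    sca_fraction: float = 0.20
    grid_rows: int = 50
    grid_cols: int = 50
    spatial_amplitude: float = 0.3  # SD of the smooth surface, trait-scale units
    spatial_length_scale: float = 10.0  # grid units
    seed: int = 0

    @property
    def deviation_fraction(self) -> float:
        return 1.0 - 2 * self.gca_fraction - self.sca_fraction

    @property
    def true_H2(self) -> float:
        return self.sigma2_G / (self.sigma2_G + self.sigma2_E)

    def validate(self):
        if min(self.sigma2_G, self.sigma2_E) < 0 or self.deviation_fraction < 0:
            raise ConfigError("variance components must be non-negative")
        n_trees = (
            self.n_mothers * self.n_fathers * self.progeny_per_family
            * self.ramets_per_genotype
        )
        if n_trees > self.grid_rows * self.grid_cols:
            raise ConfigError(
                f"layout infeasible: {n_trees} ramets > "
                f"{self.grid_rows * self.grid_cols} grid positions"
            )
        return self


XYLOSE_PEDIGREE = dict(sigma2_G=0.34, sigma2_E=0.66)


def _spatial_surface(rows: int, cols: int, amplitude: float, length_scale: float, rng):
    """Smooth random surface: superposed low-frequency cosine waves,
    standardized to SD = amplitude over the grid."""
    if amplitude == 0:
        return np.zeros((rows, cols))
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    surf = np.zeros((rows, cols))
    for _ in range(6):
        theta = rng.uniform(0, 2 * np.pi)
        freq = rng.uniform(0.3, 1.0) / length_scale
        phase = rng.uniform(0, 2 * np.pi)
        surf += rng.normal(0, 1) * np.cos(
            2 * np.pi * freq * (rr * np.cos(theta) + cc * np.sin(theta)) + phase
        )
    surf -= surf.mean()
    sd = surf.std()
    return surf * (amplitude / sd) if sd > 0 else surf


@dataclass
class PedigreeTrial:
    """Simulated trial: phenotype records per trait plus provenance."""

    records: dict[str, list[PhenotypeRecord]]
    metadata: list[SampleMetadata]
    truth: pd.DataFrame
    spectra: list[MassSpectrum] | None
    true_H2: dict[str, float]
    provenance: dict


def simulate_pedigree(
    pconfig: PedigreeSimConfig | None = None,
    gconfig: GeneratorConfig | None = None,
    xylose_pconfig: PedigreeSimConfig | None = None,
    include_spectra: bool = True,
) -> PedigreeTrial:
    """Simulate a clonally replicated factorial-cross field trial.

    Glucose and xylose phenotypes are generated on the standard trait scale
    (genotype value = GCA_m + GCA_f + SCA + deviation; ramet value adds the
    spatial surface and a residual), then mapped onto composition units via
    the generator's trait means/SDs so spectra can be composed per ramet.
    """
    pconfig = (pconfig or PedigreeSimConfig()).validate()
    gconfig = (gconfig or GeneratorConfig()).validate()
    if xylose_pconfig is None:
        xylose_pconfig = PedigreeSimConfig(
            **{**asdict(pconfig), **XYLOSE_PEDIGREE}
        ).validate()
    rng = np.random.default_rng(pconfig.seed)

    genotypes = []  # (genotype_id, mother, father)
    for mi in range(pconfig.n_mothers):
        for fi in range(pconfig.n_fathers):
            for pi in range(pconfig.progeny_per_family):
                genotypes.append((f"M{mi + 1}xF{fi + 1}_p{pi + 1}", f"M{mi + 1}", f"F{fi + 1}"))
    n_geno = len(genotypes)

    def genetic_values(cfg: PedigreeSimConfig) -> np.ndarray:
        sg = cfg.sigma2_G
        gca_m = rng.normal(0, np.sqrt(cfg.gca_fraction * sg), cfg.n_mothers)
        gca_f = rng.normal(0, np.sqrt(cfg.gca_fraction * sg), cfg.n_fathers)
        sca = rng.normal(0, np.sqrt(cfg.sca_fraction * sg), (cfg.n_mothers, cfg.n_fathers))
        dev = rng.normal(0, np.sqrt(cfg.deviation_fraction * sg), n_geno)
        g = np.empty(n_geno)
        for idx, (_, mother, father) in enumerate(genotypes):
            mi, fi = int(mother[1:]) - 1, int(father[1:]) - 1
            g[idx] = gca_m[mi] + gca_f[fi] + sca[mi, fi] + dev[idx]
        # Standardize so the genotype population realizes exactly the nominal
        # genotypic variance (founder-scaling, as quantitative-genetics
        # simulators do): with few parents the family covariance otherwise
        # shrinks the realized variance below sigma2_G, making the recorded
        # "true H2" inexact for the data actually generated.
        if sg > 0:
            g = g - g.mean()
            realized = g.var(ddof=1)
            if realized > 0:
                g = g * np.sqrt(sg / realized)
        else:
            g[:] = 0.0
        return g

    g_glc = genetic_values(pconfig)
    g_xyl = genetic_values(xylose_pconfig)

    surface = _spatial_surface(
        pconfig.grid_rows, pconfig.grid_cols, pconfig.spatial_amplitude,
        pconfig.spatial_length_scale, rng,
    )
    n_trees = n_geno * pconfig.ramets_per_genotype
    positions = rng.choice(pconfig.grid_rows * pconfig.grid_cols, n_trees, replace=False)

    # per-genotype baseline lignin / S/G from the composition model
    base_comp = sample_compositions(n_geno, gconfig, rng=rng)

    records: dict[str, list[PhenotypeRecord]] = {"glucose_dw_pct": [], "xylose_dw_pct": []}
    metadata, spectra, truth_rows = [], [], []
    tree = 0
    for idx, (gid, mother, father) in enumerate(genotypes):
        for ram in range(pconfig.ramets_per_genotype):
            pos = positions[tree]
            row, col = int(pos // pconfig.grid_cols), int(pos % pconfig.grid_cols)
            s_val = surface[row, col]
            z_glc = g_glc[idx] + s_val + rng.normal(0, np.sqrt(pconfig.sigma2_E))
            z_xyl = g_xyl[idx] + s_val + rng.normal(0, np.sqrt(xylose_pconfig.sigma2_E))
            glc = gconfig.means["glucose_dw_pct"] + gconfig.sds["glucose_dw_pct"] * z_glc
            xyl = gconfig.means["xylose_dw_pct"] + gconfig.sds["xylose_dw_pct"] * z_xyl
            sid = f"{gid}_r{ram + 1}"
            for trait, z in (("glucose_dw_pct", z_glc), ("xylose_dw_pct", z_xyl)):
                records[trait].append(
                    PhenotypeRecord(
                        genotype_id=gid, value=float(z), field_row=row, field_col=col,
                        mother_id=mother, father_id=father, ramet_id=sid,
                    )
                )
            metadata.append(
                SampleMetadata(
                    sample_id=sid, genotype_id=gid, population="pedigree",
                    mother_id=mother, father_id=father, field_row=row, field_col=col,
                    n_replicates=gconfig.n_replicates,
                )
            )
            truth_rows.append(
                {
                    "sample_id": sid, "genotype_id": gid,
                    "glucose_dw_pct": glc, "xylose_dw_pct": xyl,
                    "lignin_pct": base_comp[idx].lignin_pct,
                    "sg_ratio": base_comp[idx].sg_ratio,
                    "genetic_value_glucose": g_glc[idx],
                    "genetic_value_xylose": g_xyl[idx],
                    "spatial_effect": float(s_val),
                }
            )
            if include_spectra:
                t = CompositionTruth(
                    glucose_dw_pct=float(np.clip(glc, 1.0, 90.0)),
                    xylose_dw_pct=float(np.clip(xyl, 0.5, 40.0)),
                    lignin_pct=base_comp[idx].lignin_pct,
                    sg_ratio=base_comp[idx].sg_ratio,
                )
                for rep in range(gconfig.n_replicates):
                    spectra.append(
                        compose_spectrum(t, gconfig, rng=rng, sample_id=sid,
                                         replicate_id=str(rep + 1))
                    )
            tree += 1

    true_h2 = {"glucose_dw_pct": pconfig.true_H2, "xylose_dw_pct": xylose_pconfig.true_H2}
    prov = {
        "seed": pconfig.seed,
        "config_hash": config_hash(pconfig, gconfig),
        "true_H2": true_h2,
        "n_genotypes": n_geno,
        "n_ramets": n_trees,
    }
    return PedigreeTrial(
        records=records, metadata=metadata, truth=pd.DataFrame(truth_rows),
        spectra=spectra if include_spectra else None, true_H2=true_h2, provenance=prov,
    )


# ---------------------------------------------------------------------------
# Dataset writer
# ---------------------------------------------------------------------------


def generate_dataset(
    kind: str,
    out_dir,
    gconfig: GeneratorConfig | None = None,
    pconfig: PedigreeSimConfig | None = None,
    n_samples: int = 500,
    force: bool = False,
) -> dict:
    """Write a complete synthetic study (spectra, metadata, reference, truth).

    ``kind`` is "natural" (independent accessions) or "pedigree" (factorial
    cross on a field grid). Files: spectra.csv, metadata.csv, reference.csv,
    truth.csv and provenance.json. Refuses to overwrite without ``force``.
    """
    gconfig = (gconfig or GeneratorConfig()).validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = ["spectra.csv", "metadata.csv", "reference.csv", "truth.csv", "provenance.json"]
    existing = [f for f in files if (out / f).exists()]
    if existing and not force:
        raise FileExistsError(f"refusing to overwrite {existing} in {out} without force")

    rng = np.random.default_rng(gconfig.seed)
    if kind == "natural":
        truths = sample_compositions(n_samples, gconfig, rng=rng)
        spectra, metadata, truth_rows = [], [], []
        for i, t in enumerate(truths):
            sid = f"NV{i + 1:04d}"
            for rep in range(gconfig.n_replicates):
                spectra.append(
                    compose_spectrum(t, gconfig, rng=rng, sample_id=sid,
                                     replicate_id=str(rep + 1))
                )
            metadata.append(
                SampleMetadata(sample_id=sid, genotype_id=sid, population="natural",
                               n_replicates=gconfig.n_replicates)
            )
            truth_rows.append({"sample_id": sid, **{tr: getattr(t, tr) for tr in TRAITS}})
        truth_df = pd.DataFrame(truth_rows)
        ref = nmr_measure(truths, gconfig, rng=rng)
        ref.insert(0, "sample_id", [r["sample_id"] for r in truth_rows])
        prov = {"kind": kind, "seed": gconfig.seed, "n_samples": n_samples,
                "config_hash": config_hash(gconfig)}
    elif kind == "pedigree":
        pconfig = (pconfig or PedigreeSimConfig(seed=gconfig.seed)).validate()
        trial = simulate_pedigree(pconfig, gconfig, include_spectra=True)
        spectra, metadata, truth_df = trial.spectra, trial.metadata, trial.truth
        ref_vals = truth_df[["glucose_dw_pct", "xylose_dw_pct"]].to_numpy()
        noise = rng.normal(
            0, [gconfig.reference_sd["glucose_dw_pct"], gconfig.reference_sd["xylose_dw_pct"]],
            ref_vals.shape,
        )
        ref = pd.DataFrame(ref_vals + noise, columns=["glucose_dw_pct", "xylose_dw_pct"])
        ref.insert(0, "sample_id", truth_df["sample_id"].to_numpy())
        prov = {"kind": kind, **trial.provenance}
    else:
        raise ConfigError(f"unknown dataset kind {kind!r}")

    write_spectra(spectra, out / "spectra.csv")
    write_metadata(metadata, out / "metadata.csv")
    ref.to_csv(out / "reference.csv", index=False, float_format="%.17g")
    truth_df.to_csv(out / "truth.csv", index=False, float_format="%.17g")
    with open(out / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)
    return prov
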