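"""Synthetic targeted-metabolomics panels with known ground truth.

The generator emulates a single-plate Biocrates-p180-style experiment on
three pig breeds: 186 metabolites over seven analyte subclasses, 12 animals
per breed (castrated males and gilts), two QC replicate injections, and
log-normal concentrations with

* multiplicative breed effects on a planted subset of metabolites
  (fold changes, the ground truth for feature selection),
* linear sex and carcass-weight effects on the log scale for a random
  subset of metabolites (so covariate residualization is non-trivial),
* within-family correlation induced by a shared latent factor per block,
* per-metabolite limits of detection plus a configurable handful of
  metabolites planted to fail each QC rule (high replicate CV, all QC
  values below LOD, >30% of samples below LOD).

Everything is driven by one integer seed; identical configs give
byte-identical panels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import write_panel
from .panel import MetabolitePanel

# Analyte-class composition of the emulated 186-metabolite panel.
PANEL_COMPOSITION = {
    "AC": 40,
    "AA": 21,
    "BA": 19,
    "hexose": 1,
    "LysoPC": 14,
    "PC": 76,
    "SM": 15,
}


class SimConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of one synthetic panel.

    Defaults mirror the emulated study design: 3 breeds x 12 animals,
    186 metabolites, 2 QC replicates at ~5% intraplate CV, and one
    CV-failing, three QC-below-LOD and one samples-below-LOD metabolite.
    """

    group_names: tuple[str, ...] = ("ILA", "ILW", "IDU")
    n_per_group: int = 12
    n_metabolites: int = 186
    n_qc: int = 2

    # breed signal
    n_discriminant_per_pair: int = 6
    effect_size_range: tuple[float, float] = (1.5, 3.0)

    # log-normal baseline: log-mean in log(µM), log-sd dimensionless
    base_logmean_range: tuple[float, float] = (-2.3, 4.6)
    log_sd_range: tuple[float, float] = (0.2, 0.6)

    # covariates
    weight_mean_kg: float = 125.0
    weight_sd_kg: float = 6.0
    frac_weight_affected: float = 0.3
    weight_effect_range: tuple[float, float] = (0.005, 0.02)  # per kg, log scale
    frac_sex_affected: float = 0.3
    sex_effect_range: tuple[float, float] = (0.1, 0.4)  # log scale

    # correlation structure: latent-factor blocks within analyte classes
    block_size: int = 8
    block_rho: float = 0.5

    # QC / censoring
    qc_cv_percent: float = 5.0
    qc_fail_cv_percent: float = 35.0
    n_fail_cv: int = 1
    n_fail_lod_qc: int = 3
    n_fail_lod_samples: int = 1
    lod_quantile: float = 0.02
    na_frac: float = 0.0

    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1 or self.n_metabolites < 1 or self.n_qc < 0:
            raise SimConfigError("counts must be >= 1 (n_qc >= 0)")
        if len(self.group_names) < 2:
            raise SimConfigError("need at least two groups")
        n_pairs = len(self.group_names) * (len(self.group_names) - 1) // 2
        planted = self.n_discriminant_per_pair * n_pairs
        reserved = self.n_fail_cv + self.n_fail_lod_qc + self.n_fail_lod_samples
        if planted + reserved > self.n_metabolites:
            raise SimConfigError(
                f"{planted} discriminant + {reserved} QC-failing metabolites "
                f"exceed panel size {self.n_metabolites}"
            )
        if not 0 <= self.block_rho < 1:
            raise SimConfigError("block_rho must be in [0, 1)")
        if self.qc_cv_percent < 0:
            raise SimConfigError("qc_cv_percent must be >= 0")
        lo, hi = self.effect_size_range
        if lo <= 0:
            raise SimConfigError("effect sizes must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated panel.

    ``discriminant_sets`` maps each ordered pair label (``"ILA-ILW"``) to the
    metabolites whose log-means differ between the two groups, with the
    multiplicative effect size (fold change > 1, direction-free).
    """

    discriminant_sets: dict[str, dict[str, float]]
    covariate_effects: dict[str, dict[str, float]]
    correlation_blocks: list[dict]
    planted_qc_failures: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @staticmethod
    def from_json(path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return SyntheticTruth(**d)

    def discriminants_for(self, g1: str, g2: str) -> dict[str, float]:
        key = f"{g1}-{g2}"
        if key in self.discriminant_sets:
            return self.discriminant_sets[key]
        return self.discriminant_sets.get(f"{g2}-{g1}", {})

    def all_discriminants(self) -> set[str]:
        out: set[str] = set()
        for d in self.discriminant_sets.values():
            out |= set(d)
        return out


def _metabolite_names(cfg: SimConfig) -> tuple[list[str], list[str]]:
    """Names and analyte classes, composition proportional to the p180 panel."""
    total = sum(PANEL_COMPOSITION.values())
    counts = {
        cls: max(1 if cls != "hexose" else 0, round(cfg.n_metabolites * n / total))
        for cls, n in PANEL_COMPOSITION.items()
    }
    # adjust rounding drift on the largest class
    drift = cfg.n_metabolites - sum(counts.values())
    counts["PC"] += drift
    if counts["PC"] < 0:
        raise SimConfigError("n_metabolites too small for the panel composition")
    names, classes = [], []
    for cls in PANEL_COMPOSITION:
        for i in range(counts[cls]):
            names.append(f"{cls}_{i + 1:02d}")
            classes.append(cls)
    return names, classes


def _sex_vector(cfg: SimConfig) -> list[str]:
    """Castrated males (M) / gilts (F) per group; first group 5M/7F at n=12."""
    sexes: list[str] = []
    for gi in range(len(cfg.group_names)):
        n = cfg.n_per_group
        males = n // 2
        if gi == 0 and n >= 4:
            males -= 1
        sexes.extend(["M"] * males + ["F"] * (n - males))
    return sexes


def generate_panel(cfg: SimConfig) -> tuple[MetabolitePanel, SyntheticTruth]:
    """Draw one panel plus its ground truth; fully determined by ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    names, classes = _metabolite_names(cfg)
    m = len(names)
    groups = list(cfg.group_names)
    n_bio = cfg.n_per_group * len(groups)

    logmu = rng.uniform(*cfg.base_logmean_range, size=m)
    logsd = rng.uniform(*cfg.log_sd_range, size=m)

    # reserve QC-failing metabolites first so they never carry breed signal
    order = rng.permutation(m)
    cursor = 0

    def take(k: int) -> list[int]:
        nonlocal cursor
        out = order[cursor:cursor + k].tolist()
        cursor += k
        return out

    fail_cv = take(cfg.n_fail_cv)
    fail_lod_qc = take(cfg.n_fail_lod_qc)
    fail_lod_samples = take(cfg.n_fail_lod_samples)

    # breed effects: per pair, shift the log-mean of one randomly chosen
    # side for n_discriminant_per_pair fresh metabolites
    shift = np.zeros((len(groups), m))
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    for a, b in pairs:
        for j in take(cfg.n_discriminant_per_pair):
            fold = rng.uniform(*cfg.effect_size_range)
            target = a if rng.random() < 0.5 else b
            shift[groups.index(target), j] += np.log(fold)

    # covariate effects
    bw = np.zeros(m)
    bs = np.zeros(m)
    w_idx = rng.random(m) < cfg.frac_weight_affected
    s_idx = rng.random(m) < cfg.frac_sex_affected
    bw[w_idx] = rng.uniform(*cfg.weight_effect_range, size=w_idx.sum()) * rng.choice(
        [-1.0, 1.0], size=w_idx.sum()
    )
    bs[s_idx] = rng.uniform(*cfg.sex_effect_range, size=s_idx.sum()) * rng.choice(
        [-1.0, 1.0], size=s_idx.sum()
    )

    # correlation blocks within analyte classes
    blocks: list[list[int]] = []
    if cfg.block_size >= 2 and cfg.block_rho > 0:
        by_class: dict[str, list[int]] = {}
        for j, cls in enumerate(classes):
            by_class.setdefault(cls, []).append(j)
        for cls, idx in by_class.items():
            for start in range(0, len(idx) - cfg.block_size + 1, cfg.block_size):
                blocks.append(idx[start:start + cfg.block_size])
    block_of = np.full(m, -1)
    for bi, members in enumerate(blocks):
        block_of[members] = bi

    # covariates of the biological samples
    sexes = _sex_vector(cfg)
    sex01 = np.array([1.0 if s == "M" else 0.0 for s in sexes])
    weight = rng.normal(cfg.weight_mean_kg, cfg.weight_sd_kg, size=n_bio)
    weight = np.clip(weight, 50.0, None)
    group_of = np.repeat(np.arange(len(groups)), cfg.n_per_group)

    # latent noise: shared block factor + idiosyncratic
    z_block = rng.standard_normal((n_bio, max(len(blocks), 1)))
    eps = rng.standard_normal((n_bio, m))
    rho = cfg.block_rho
    u = eps.copy()
    for j in range(m):
        if block_of[j] >= 0:
            u[:, j] = np.sqrt(rho) * z_block[:, block_of[j]] + np.sqrt(1 - rho) * eps[:, j]

    logc = (
        logmu[None, :]
        + shift[group_of, :]
        + bw[None, :] * (weight - cfg.weight_mean_kg)[:, None]
        + bs[None, :] * sex01[:, None]
        + logsd[None, :] * u
    )
    conc = np.exp(logc)

    # QC replicates from a common latent profile with the configured CV
    qc_latent = np.exp(logmu.copy())
    qc_latent[fail_lod_samples] = np.exp(logmu[fail_lod_samples] + logsd[fail_lod_samples])
    cv = np.full(m, cfg.qc_cv_percent)
    cv[fail_cv] = cfg.qc_fail_cv_percent
    sigma_qc = np.sqrt(np.log1p((cv / 100.0) ** 2))
    qc_vals = qc_latent[None, :] * np.exp(
        rng.standard_normal((cfg.n_qc, m)) * sigma_qc[None, :]
    )
    # with few replicates the sample CV is noisy; pin the planted CV
    # failures to their target so the exclusion is not left to chance
    if cfg.n_qc >= 2:
        for j in fail_cv:
            v = qc_vals[:, j]
            mu_v, sd_v = v.mean(), v.std(ddof=1)
            if sd_v > 0:
                k = (cfg.qc_fail_cv_percent / 100.0 * mu_v) / sd_v
                qc_vals[:, j] = np.maximum(mu_v + (v - mu_v) * k, mu_v * 0.01)

    # limits of detection
    lod = np.exp(logmu + logsd * stats.norm.ppf(cfg.lod_quantile))
    if cfg.n_qc > 0:
        lod[fail_lod_qc] = qc_vals[:, fail_lod_qc].max(axis=0) * 1.5
    for j in fail_lod_samples:
        lod[j] = np.quantile(conc[:, j], 0.4)

    # optional missingness on biological cells
    if cfg.na_frac > 0:
        mask = rng.random(conc.shape) < cfg.na_frac
        conc = np.where(mask, np.nan, conc)

    sample_ids = [f"{groups[g]}{i % cfg.n_per_group + 1:02d}"
                  for i, g in enumerate(group_of)]
    qc_ids = [f"QC{i + 1}" for i in range(cfg.n_qc)]
    all_ids = pd.Index(sample_ids + qc_ids, name="sample_id")

    conc_df = pd.DataFrame(
        np.vstack([conc, qc_vals]) if cfg.n_qc else conc,
        index=all_ids, columns=names,
    )
    smeta = pd.DataFrame(
        {
            "group": [groups[g] for g in group_of] + ["QC"] * cfg.n_qc,
            "sex": sexes + ["NA"] * cfg.n_qc,
            "carcass_weight": np.concatenate([weight, np.full(cfg.n_qc, np.nan)]),
            "is_qc": [False] * n_bio + [True] * cfg.n_qc,
        },
        index=all_ids,
    )
    mmeta = pd.DataFrame(
        {"analyte_class": classes, "lod": lod},
        index=pd.Index(names, name="name"),
    )
    panel = MetabolitePanel(conc_df, smeta, mmeta)

    # ground truth from the realized log-mean shifts
    discriminant_sets: dict[str, dict[str, float]] = {}
    for a, b in pairs:
        diff = shift[groups.index(a)] - shift[groups.index(b)]
        discriminant_sets[f"{a}-{b}"] = {
            names[j]: float(np.exp(abs(diff[j])))
            for j in np.flatnonzero(np.abs(diff) > 1e-12)
        }
    truth = SyntheticTruth(
        discriminant_sets=discriminant_sets,
        covariate_effects={
            names[j]: {"beta_weight": float(bw[j]), "beta_sex": float(bs[j])}
            for j in range(m)
            if bw[j] != 0 or bs[j] != 0
        },
        correlation_blocks=[
            {"members": [names[j] for j in members], "rho": float(rho)}
            for members in blocks
        ],
        planted_qc_failures={
            "CV": [names[j] for j in fail_cv],
            "LOD_QC": [names[j] for j in fail_lod_qc],
            "LOD_SAMPLES": [names[j] for j in fail_lod_samples],
        },
    )
    return panel, truth


# ---------------------------------------------------------------------------
# fixture catalogue

def fixture_configs(base_seed: int = 0) -> dict[str, SimConfig]:
    """Named small panels covering the regimes tests and docs exercise."""
    small = dict(n_metabolites=40, n_per_group=12,
                 n_fail_cv=0, n_fail_lod_qc=0, n_fail_lod_samples=0)
    return {
        "null": SimConfig(**small, n_discriminant_per_pair=0, seed=base_seed),
        "strong_signal": SimConfig(
            **small, n_discriminant_per_pair=4,
            effect_size_range=(3.0, 4.0), seed=base_seed + 1,
        ),
        "confounded": SimConfig(
            **small, n_discriminant_per_pair=4,
            effect_size_range=(2.0, 3.0),
            frac_weight_affected=0.8, weight_effect_range=(0.02, 0.04),
            frac_sex_affected=0.5, sex_effect_range=(0.3, 0.6),
            seed=base_seed + 2,
        ),
        "censored": SimConfig(
            n_metabolites=40, n_per_group=12, n_discriminant_per_pair=2,
            n_fail_cv=1, n_fail_lod_qc=2, n_fail_lod_samples=1,
            lod_quantile=0.15, seed=base_seed + 3,
        ),
    }


def make_fixture_suite(out_dir, base_seed: int = 0) -> dict:
    """Write the fixture catalogue (panel + metadata + truth + manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    for name, cfg in fixture_configs(base_seed).items():
        panel, truth = generate_panel(cfg)
        paths = {
            "panel": f"{name}.panel.tsv",
            "meta": f"{name}.metabolites.tsv",
            "truth": f"{name}.truth.json",
        }
        write_panel(panel, out / paths["panel"], meta_path=out / paths["meta"])
        truth.to_json(out / paths["truth"])
        manifest[name] = {"seed": cfg.seed, "config": dataclasses.asdict(cfg),
                          "files": paths}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
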