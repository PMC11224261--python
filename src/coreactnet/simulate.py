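"""Synthetic tagged-cell count datasets with known ground truth.

The generator emulates a dual-epoch activity-tagging fear-conditioning design:
three experimental groups (two conditioned, one homecage control) of 6-7
animals, 15 brain regions, and per animal x region counts of DAPI+, Td+
(learning-tagged), c-Fos+ (retrieval-active), and double-labeled cells.

Model. For each animal a Gaussian latent field z ~ N(0, C) over regions
(Gaussian copula) modulates the marginal labeling rates through a lognormal
multiplier exp(sigma*z - sigma^2/2); Td+ and c-Fos+ counts are binomial at the
modulated rates, and double-labeled counts are binomial at
ratio * (n_td/n_dapi) * (n_cfos/n_dapi), clamped to feasibility (clamps are
counted, and configs that clamp more than ``max_clamp_frac`` of cells fail
fast). Because the lognormal transform and binomial counting noise distort and
attenuate the Pearson correlation of the realized double-labeled percentages,
the latent correlation is analytically pre-calibrated (inverse
lognormal-correlation map plus a variance-ratio attenuation estimate, then
projection to the nearest unit-diagonal PSD matrix) so that realized
correlations track the configured target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .io import DEFAULT_REGIONS, ValidationError

_EIG_TOL = -1e-8


@dataclass
class GroupSpec:
    name: str
    n_animals: int


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a synthetic tagging study.

    ``p_td``, ``p_cfos`` and ``ratio`` may be scalars, per-region dicts, or
    dicts keyed by (group, region); ``corr`` is one region x region target
    correlation matrix for all groups or a dict group -> matrix.
    """

    groups: list
    regions: list = field(default_factory=lambda: list(DEFAULT_REGIONS.items()))
    dapi_mean: float = 5000.0
    p_td: object = 0.06
    p_cfos: object = 0.025
    ratio: object = 1.0
    sigma_animal: float = 0.3
    corr: object = None
    seed: int = 0
    max_clamp_frac: float = 0.01

    def __post_init__(self):
        self.groups = [g if isinstance(g, GroupSpec) else GroupSpec(**g) for g in self.groups]
        self.regions = [tuple(r) for r in self.regions]

    @property
    def region_names(self) -> list:
        return [r for r, _ in self.regions]

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(self.regions, columns=["region", "anatomical_group"])

    def corr_for(self, group: str) -> np.ndarray:
        n = len(self.regions)
        if self.corr is None:
            return np.eye(n)
        c = self.corr[group] if isinstance(self.corr, dict) else self.corr
        return np.asarray(c, dtype=float)

    def param(self, name: str, group: str, region: str) -> float:
        value = getattr(self, name)
        if isinstance(value, dict):
            for key in ((group, region), region, group):
                if key in value:
                    return float(value[key])
            raise ValidationError(f"{name} has no entry for group {group!r}, region {region!r}")
        return float(value)

    def validate(self) -> None:
        if not self.groups:
            raise ValidationError("at least one group is required")
        if not self.regions:
            raise ValidationError("at least one region is required")
        if self.dapi_mean <= 0:
            raise ValidationError("dapi_mean must be positive")
        if self.sigma_animal < 0:
            raise ValidationError("sigma_animal must be non-negative")
        for g in self.groups:
            if g.n_animals < 1:
                raise ValidationError(f"group {g.name!r} has no animals")
            c = self.corr_for(g.name)
            n = len(self.regions)
            if c.shape != (n, n):
                raise ValidationError(
                    f"corr for group {g.name!r} has shape {c.shape}, expected {(n, n)}"
                )
            if not np.allclose(c, c.T, atol=1e-10):
                raise ValidationError(f"corr for group {g.name!r} is not symmetric")
            if not np.allclose(np.diag(c), 1.0, atol=1e-8):
                raise ValidationError(f"corr for group {g.name!r} does not have a unit diagonal")
            eig = np.linalg.eigvalsh(c)
            if eig.min() < _EIG_TOL:
                raise ValidationError(
                    f"corr for group {g.name!r} is not positive semidefinite: "
                    f"offending eigenvalue {eig.min():.6g}"
                )
            for region in self.region_names:
                for p_name in ("p_td", "p_cfos"):
                    p = self.param(p_name, g.name, region)
                    if not 0.0 < p < 1.0:
                        raise ValidationError(
                            f"{p_name}={p} for group {g.name!r}, region {region!r} "
                            "must lie in (0, 1)"
                        )
                if self.param("ratio", g.name, region) < 0:
                    raise ValidationError(
                        f"ratio for group {g.name!r}, region {region!r} must be >= 0"
                    )

    # -- yaml round trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        def plain(v):
            if isinstance(v, dict):
                return {"|".join(k) if isinstance(k, tuple) else k: float(x) for k, x in v.items()}
            return float(v)

        doc = {
            "groups": [{"name": g.name, "n_animals": int(g.n_animals)} for g in self.groups],
            "regions": [list(r) for r in self.regions],
            "dapi_mean": float(self.dapi_mean),
            "p_td": plain(self.p_td),
            "p_cfos": plain(self.p_cfos),
            "ratio": plain(self.ratio),
            "sigma_animal": float(self.sigma_animal),
            "corr": (
                None
                if self.corr is None
                else {g.name: np.asarray(self.corr_for(g.name)).tolist() for g in self.groups}
            ),
            "seed": int(self.seed),
            "max_clamp_frac": float(self.max_clamp_frac),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)

        def unplain(v):
            if isinstance(v, dict):
                return {tuple(k.split("|")) if "|" in k else k: x for k, x in v.items()}
            return v

        for key in ("p_td", "p_cfos", "ratio"):
            if key in doc:
                doc[key] = unplain(doc[key])
        if doc.get("corr") is not None:
            doc["corr"] = {g: np.asarray(m, dtype=float) for g, m in doc["corr"].items()}
        return cls(**doc)


# ---------------------------------------------------------------------------
# latent-correlation calibration


def _nearest_unit_psd(c: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and rescale to a unit diagonal."""
    w, v = np.linalg.eigh((c + c.T) / 2.0)
    w = np.clip(w, 1e-9, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def _calibrate_latent(cfg: SimulationConfig, group: str) -> tuple[np.ndarray, int]:
    """Latent normal correlation that yields the target double_pct correlation.

    Inverts the lognormal pairwise-correlation map and compensates the
    attenuation from binomial counting noise (estimated analytically from the
    expected per-cell variance); unreachable targets are capped, and the capped
    pair count returned.
    """
    target = cfg.corr_for(group)
    n = len(cfg.regions)
    sigma = cfg.sigma_animal
    if sigma == 0:
        if not np.allclose(target, np.eye(n), atol=1e-12):
            raise ValidationError(
                "sigma_animal=0 leaves no animal-level variation to correlate; "
                "a non-identity corr target is unreachable"
            )
        return np.eye(n), 0
    s2 = (2.0 * sigma) ** 2  # double-label multiplier is exp(2*sigma*z - sigma^2)

    lam = np.empty(n)
    for i, region in enumerate(cfg.region_names):
        p_td = cfg.param("p_td", group, region)
        p_cfos = cfg.param("p_cfos", group, region)
        ratio = cfg.param("ratio", group, region)
        mu = 100.0 * ratio * p_td * p_cfos * np.exp(sigma**2)  # mean double_pct
        var_rate = mu**2 * (np.exp(s2) - 1.0)
        if mu == 0 or var_rate == 0:
            lam[i] = 0.0
            continue
        nd = cfg.dapi_mean
        noise = (
            100.0 * mu / nd  # binomial noise of the double draw, percent^2
            + mu**2 * (1.0 - p_td) / (nd * p_td)  # propagated Td+ noise
            + mu**2 * (1.0 - p_cfos) / (nd * p_cfos)  # propagated c-Fos+ noise
        )
        lam[i] = np.sqrt(var_rate / (var_rate + noise))

    latent = np.eye(n)
    n_capped = 0
    for i in range(n):
        for j in range(i + 1, n):
            t = target[i, j]
            if t == 0:
                continue
            if lam[i] == 0 or lam[j] == 0:
                n_capped += 1
                continue
            rho_rate = t / (lam[i] * lam[j])
            if abs(rho_rate) > 0.99:
                rho_rate = np.sign(rho_rate) * 0.99
                n_capped += 1
            rho_z = np.log1p(rho_rate * (np.exp(s2) - 1.0)) / s2
            latent[i, j] = latent[j, i] = np.clip(rho_z, -0.999, 0.999)
    return _nearest_unit_psd(latent), n_capped


# ---------------------------------------------------------------------------
# generation


def generate_dataset(cfg: SimulationConfig, seed: int | None = None):
    """Draw one dataset; returns (counts DataFrame, ground-truth dict).

    ``seed`` overrides ``cfg.seed``. The ground truth records every planted
    parameter, the calibrated latent correlations, and clamp counts; config +
    seed fully determine the dataset.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_regions = len(cfg.regions)
    region_names = cfg.region_names
    sigma = cfg.sigma_animal

    rows = []
    truth_groups = {}
    total_cells = 0
    total_clamped = 0
    for g in cfg.groups:
        latent_corr, n_capped = _calibrate_latent(cfg, g.name)
        chol = np.linalg.cholesky(latent_corr + 1e-10 * np.eye(n_regions))
        p_td = np.array([cfg.param("p_td", g.name, r) for r in region_names])
        p_cfos = np.array([cfg.param("p_cfos", g.name, r) for r in region_names])
        ratio = np.array([cfg.param("ratio", g.name, r) for r in region_names])

        z = rng.standard_normal((g.n_animals, n_regions)) @ chol.T
        mult = np.exp(sigma * z - sigma**2 / 2.0)
        n_dapi = np.maximum(1, rng.poisson(cfg.dapi_mean, size=(g.n_animals, n_regions)))
        n_td = rng.binomial(n_dapi, np.clip(p_td * mult, 1e-12, 0.999))
        n_cfos = rng.binomial(n_dapi, np.clip(p_cfos * mult, 1e-12, 0.999))
        f_td = n_td / n_dapi
        f_cfos = n_cfos / n_dapi
        p_dbl_raw = ratio * f_td * f_cfos
        feasible = np.minimum(f_td, f_cfos)
        clamped = p_dbl_raw > feasible
        total_clamped += int(clamped.sum())
        total_cells += clamped.size
        n_double = rng.binomial(n_dapi, np.minimum(p_dbl_raw, feasible))
        n_double = np.minimum(n_double, np.minimum(n_td, n_cfos))

        for a in range(g.n_animals):
            animal = f"{g.name}_{a + 1:02d}"
            for r in range(n_regions):
                rows.append(
                    (
                        animal,
                        g.name,
                        region_names[r],
                        int(n_dapi[a, r]),
                        int(n_td[a, r]),
                        int(n_cfos[a, r]),
                        int(n_double[a, r]),
                    )
                )
        truth_groups[g.name] = {
            "n_animals": g.n_animals,
            "p_td": p_td.tolist(),
            "p_cfos": p_cfos.tolist(),
            "ratio": ratio.tolist(),
            "target_corr": cfg.corr_for(g.name).tolist(),
            "latent_corr": latent_corr.tolist(),
            "n_capped_pairs": n_capped,
            "n_clamped_cells": int(clamped.sum()),
        }

    clamp_frac = total_clamped / total_cells
    if clamp_frac > cfg.max_clamp_frac:
        raise ValidationError(
            f"{clamp_frac:.1%} of cells required clamping the double-label rate "
            f"(limit {cfg.max_clamp_frac:.1%}); the configured ratios are infeasible"
        )

    counts = pd.DataFrame(
        rows, columns=["animal_id", "group", "region", "n_dapi", "n_td", "n_cfos", "n_double"]
    )
    ground_truth = {
        "seed": int(cfg.seed if seed is None else seed),
        "dapi_mean": cfg.dapi_mean,
        "sigma_animal": sigma,
        "regions": [list(r) for r in cfg.regions],
        "groups": truth_groups,
        "clamp_fraction": clamp_frac,
    }
    return counts, ground_truth


def write_ground_truth(ground_truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(ground_truth, fh, indent=2)


# ---------------------------------------------------------------------------
# presets and planted structures


def block_corr_matrix(
    n: int, block: list, value: float, background: float = 0.1
) -> np.ndarray:
    """Unit-diagonal matrix with constant background and one high block.

    ``block`` are the indices whose mutual correlations are raised to
    ``value``. Raising off-diagonals by adding rank-one blocks keeps the
    matrix PSD for the defaults used here; the construction is validated by
    the config check either way.
    """
    c = np.full((n, n), background)
    idx = np.asarray(block, dtype=int)
    if idx.size:
        c[np.ix_(idx, idx)] = value
    np.fill_diagonal(c, 1.0)
    return c


# Table-scale marginal labeling rates per region (fraction of DAPI+ cells):
# learning-tag (Td+) rates from training, retrieval (c-Fos+) rates from test,
# separately for the two conditioned groups and the homecage control.
_STUDY_P_TD = {
    "CFC": dict(AC=0.0717, PL=0.0741, IL=0.0481, BLA=0.1006, BMA=0.0912, CEA=0.1587,
                LA=0.0506, MEA=0.1252, dCA1=0.0124, dDG=0.0585, vCA1=0.0241, vDG=0.0190,
                vSUB=0.0383, PER_35=0.0833, PER_36=0.0777),
    "CFC-5s": dict(AC=0.0703, PL=0.0590, IL=0.0498, BLA=0.0771, BMA=0.0913, CEA=0.1137,
                   LA=0.0367, MEA=0.1081, dCA1=0.0116, dDG=0.0520, vCA1=0.0194, vDG=0.0238,
                   vSUB=0.0457, PER_35=0.0766, PER_36=0.0558),
    "HC": dict(AC=0.0415, PL=0.0302, IL=0.0258, BLA=0.0148, BMA=0.0285, CEA=0.0254,
               LA=0.0127, MEA=0.0280, dCA1=0.0057, dDG=0.0298, vCA1=0.0050, vDG=0.0053,
               vSUB=0.0020, PER_35=0.0160, PER_36=0.0295),
}
_STUDY_P_CFOS = {
    "CFC": dict(AC=0.0200, PL=0.0374, IL=0.0257, BLA=0.0377, BMA=0.0408, CEA=0.0236,
                LA=0.0246, MEA=0.0474, dCA1=0.0043, dDG=0.0274, vCA1=0.0155, vDG=0.0134,
                vSUB=0.0347, PER_35=0.0476, PER_36=0.0519),
    "CFC-5s": dict(AC=0.0173, PL=0.0269, IL=0.0233, BLA=0.0239, BMA=0.0333, CEA=0.0220,
                   LA=0.0151, MEA=0.0461, dCA1=0.0067, dDG=0.0301, vCA1=0.0132, vDG=0.0132,
                   vSUB=0.0355, PER_35=0.0322, PER_36=0.0308),
    "HC": dict(AC=0.0072, PL=0.0102, IL=0.0121, BLA=0.0079, BMA=0.0146, CEA=0.0056,
               LA=0.0058, MEA=0.0070, dCA1=0.0021, dDG=0.0158, vCA1=0.0019, vDG=0.0010,
               vSUB=0.0012, PER_35=0.0091, PER_36=0.0144),
}


def study_like_config(seed: int = 0) -> SimulationConfig:
    """Configuration emulating the study design with planted network structure.

    Three groups (CFC n=7, CFC-5s n=6, HC n=6), the default 15-region panel,
    marginal rates in the study's percentage range, above-chance reactivation
    (ratio 1.8) in the conditioned groups and chance-level (ratio 1) in the
    homecage group, a high amygdala-PH co-reactivation block planted in the
    CFC-5s-like group and a hippocampus-PH block in the CFC-like group.
    """
    regions = list(DEFAULT_REGIONS.items())
    names = [r for r, _ in regions]
    anat = dict(regions)
    amy_ph = [i for i, r in enumerate(names) if anat[r] in ("amygdala", "PH")]
    hpc_ph = [i for i, r in enumerate(names) if anat[r] in ("hippocampus", "PH")]
    p_td = {(g, r): v for g, d in _STUDY_P_TD.items() for r, v in d.items()}
    p_cfos = {(g, r): v for g, d in _STUDY_P_CFOS.items() for r, v in d.items()}
    return SimulationConfig(
        groups=[GroupSpec("CFC", 7), GroupSpec("CFC-5s", 6), GroupSpec("HC", 6)],
        regions=regions,
        dapi_mean=5000.0,
        p_td=p_td,
        p_cfos=p_cfos,
        ratio={"CFC": 1.8, "CFC-5s": 1.8, "HC": 1.0},
        sigma_animal=0.3,
        corr={
            "CFC": block_corr_matrix(15, hpc_ph, 0.75, background=0.2),
            "CFC-5s": block_corr_matrix(15, amy_ph, 0.75, background=0.2),
            "HC": block_corr_matrix(15, [], 0.0, background=0.1),
        },
        seed=seed,
    )


def preset_study_like(seed: int = 0):
    """One study-like dataset: (counts, region metadata, ground truth)."""
    cfg = study_like_config(seed)
    counts, truth = generate_dataset(cfg)
    return counts, cfg.metadata(), truth


def planted_hub_network(
    n_nodes: int = 15,
    n_hubs: int = 2,
    advantage: float = 3.0,
    weight_range: tuple = (0.05, 0.25),
    seed: int = 0,
):
    """Complete weighted network with planted high-strength hub nodes.

    Background edge weights are uniform on ``weight_range``; every edge
    incident to a planted hub is scaled by ``advantage`` (capped at 0.95).
    Returns (graph, hub node list); node placement is randomized by ``seed``.
    """
    if not 0 < n_hubs < n_nodes:
        raise ValidationError("n_hubs must lie strictly between 0 and n_nodes")
    rng = np.random.default_rng(seed)
    names = [f"R{i + 1:02d}" for i in range(n_nodes)]
    hubs = list(rng.choice(names, size=n_hubs, replace=False))
    g = nx.Graph(sign_mode="positive", group="planted")
    g.add_nodes_from(names)
    lo, hi = weight_range
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            w = rng.uniform(lo, hi)
            if names[i] in hubs or names[j] in hubs:
                w = min(0.95, w * advantage)
            g.add_edge(names[i], names[j], weight=float(w), r=float(w))
    return g, hubs
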