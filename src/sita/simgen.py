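"""Synthetic root time-lapse traces and structured genotype panels.

The root simulator is a first-order relaxation of the tip heading toward
a treatment-dependent setpoint — the simplest stochastic process whose
tip-direction trajectory follows the exponential-decay kinetics fitted
downstream.  It is a stand-in for real gravistimulated roots, not a
biological model: per frame the heading (degrees from gravity) updates as

    theta <- theta + g_rate * dt * (theta_set - theta) + eps,
    eps ~ Normal(0, sigma_theta^2 * dt),

and the tip advances ``v * dt`` cm along the heading (image convention,
gravity = +y).  Under control the setpoint is 0 (straight down); under
NaCl it is a nonzero deflection whose sign is an exposed parameter.

The genotype simulator draws subpopulation allele frequencies by the
Balding-Nichols construction and plants one causal SNP plus a polygenic
term, so every downstream association stage can be tested against known
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .traits import RootPolyline, RootTimeSeries

__all__ = [
    "RootSimConfig",
    "PanelSimConfig",
    "GenotypePanel",
    "simulate_root",
    "simulate_panel",
]

TREATMENTS = ("control", "NaCl")


@dataclass
class RootSimConfig:
    """Parameters of the heading-relaxation root simulator.

    Defaults emulate the assay's study conditions: imaging every 20 min
    (dt = 1/3 h) over 24 h, a 90-degree tilt (initial heading 90 deg from
    gravity), and a positive salt setpoint (deflection toward +x).
    """

    n_plants: int = 30
    duration_h: float = 24.0
    dt_h: float = 1.0 / 3.0
    v_mean: float = 0.035          # cm/h, typical seedling root extension
    v_sd: float = 0.005
    theta0_deg: float = 90.0       # heading right after the 90-degree tilt
    g_rate: float = 0.3            # 1/h relaxation toward the setpoint
    theta_set_control_deg: float = 0.0
    theta_set_salt_deg: float = 45.0
    sigma_theta: float = 3.0       # deg / sqrt(h) heading noise
    seed: int = 0

    def validate(self) -> None:
        for name in ("duration_h", "dt_h", "v_mean", "v_sd", "theta0_deg",
                     "g_rate", "theta_set_control_deg", "theta_set_salt_deg",
                     "sigma_theta"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite config value: {name}")
        if self.dt_h <= 0:
            raise ValueError("dt_h must be > 0")
        if self.duration_h < self.dt_h:
            raise ValueError("duration_h must be >= dt_h")
        if self.v_mean <= 0:
            raise ValueError("v_mean must be > 0")
        if self.sigma_theta < 0 or self.g_rate < 0:
            raise ValueError("sigma_theta and g_rate must be >= 0")


@dataclass
class PanelSimConfig:
    """Parameters of the structured diploid genotype/phenotype simulator."""

    n_acc: int = 300
    n_snp: int = 5000
    n_subpop: int = 2
    fst: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_snp: float = 0.15
    h2_poly: float = 0.3
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_acc < 2 or self.n_snp < 1 or self.n_subpop < 1:
            raise ValueError("n_acc >= 2, n_snp >= 1, n_subpop >= 1 required")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.h2_snp < 1.0 and 0.0 <= self.h2_poly < 1.0):
            raise ValueError("heritabilities must be in [0, 1)")
        if self.h2_snp + self.h2_poly >= 1.0:
            raise ValueError("infeasible variance decomposition: "
                             "h2_snp + h2_poly must be < 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class GenotypePanel:
    """Accessions x SNPs biallelic dosage matrix with marker metadata.

    ``dosages`` holds 0/1/2 alt-allele counts as floats, NaN for missing.
    """

    dosages: np.ndarray
    accession_ids: list[str]
    markers: "pd.DataFrame"  # columns: chrom, pos, id, ref, alt

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=float)
        if d.ndim != 2:
            raise ValueError("dosages must be 2-D (accessions x SNPs)")
        if d.shape[0] != len(self.accession_ids):
            raise ValueError("accession count mismatch")
        if d.shape[1] != len(self.markers):
            raise ValueError("marker count mismatch")
        if self.markers["id"].duplicated().any():
            raise ValueError("duplicate marker ids")
        if (self.markers["pos"] < 0).any():
            raise ValueError("negative marker position")
        ok = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        self.dosages = d

    @property
    def n_acc(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snp(self) -> int:
        return self.dosages.shape[1]

    def subset_snps(self, mask: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            self.dosages[:, mask],
            list(self.accession_ids),
            self.markers.loc[mask].reset_index(drop=True),
        )


def simulate_root(config: RootSimConfig, treatment: str,
                  seed: int | None = None) -> RootTimeSeries:
    """Simulate one root's time-lapse trace under a treatment.

    Returns a :class:`RootTimeSeries` on the grid {0, dt, 2*dt, ...};
    each frame's polyline extends the previous one (earlier points are
    immutable, as in incremental tracing).  The per-frame ground-truth
    heading sequence is attached as ``series.headings_deg``.
    """
    config.validate()
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}; "
                         f"expected one of {TREATMENTS}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    theta_set = (config.theta_set_control_deg if treatment == "control"
                 else config.theta_set_salt_deg)
    dt = config.dt_h
    n_frames = int(round(config.duration_h / dt)) + 1
    v = max(rng.normal(config.v_mean, config.v_sd), 0.2 * config.v_mean)

    theta = config.theta0_deg
    headings = [theta]
    # short initial segment along theta0 so frame 0 is a valid polyline
    seed_len = 0.05
    rad0 = math.radians(theta)
    pts = [np.array([-seed_len * math.sin(rad0), -seed_len * math.cos(rad0)]),
           np.array([0.0, 0.0])]
    plant_id = f"plant{rng.integers(0, 10**9):09d}"
    frames = [RootPolyline(np.array(pts), plant_id=plant_id, time_h=0.0)]
    for i in range(1, n_frames):
        noise = rng.normal(0.0, config.sigma_theta * math.sqrt(dt))
        theta = theta + config.g_rate * dt * (theta_set - theta) + noise
        headings.append(theta)
        rad = math.radians(theta)
        step = v * dt * np.array([math.sin(rad), math.cos(rad)])
        pts.append(pts[-1] + step)
        frames.append(RootPolyline(np.array(pts), plant_id=plant_id,
                                   time_h=i * dt))
    return RootTimeSeries(frames, treatment=treatment,
                          headings_deg=np.array(headings))


def _balding_nichols_freqs(rng: np.random.Generator, n_snp: int,
                           n_subpop: int, fst: float,
                           maf_range: tuple[float, float]) -> np.ndarray:
    """Subpopulation allele frequencies (n_subpop x n_snp)."""
    lo, hi = maf_range
    p_anc = rng.uniform(lo, hi, size=n_snp)
    if fst == 0.0:
        return np.tile(p_anc, (n_subpop, 1))
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    freqs = rng.beta(a, b, size=(n_subpop, n_snp))
    return np.clip(freqs, 1e-4, 1.0 - 1e-4)


def simulate_panel(config: PanelSimConfig
                   ) -> tuple[GenotypePanel, np.ndarray, dict[str, Any]]:
    """Simulate a structured genotype panel with one planted causal SNP.

    The phenotype is ``beta * x_causal + u + e`` with ``u`` drawn from a
    multivariate normal whose covariance is the realized genomic kinship
    and ``beta`` scaled so the causal SNP explains ``h2_snp`` of the
    total phenotypic variance.  Total variance is normalized to 1.

    Returns ``(panel, phenotype, truth)`` where ``truth`` records the
    causal index, beta, and the variance components.
    """
    import pandas as pd

    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_acc, config.n_snp

    subpop = np.repeat(np.arange(config.n_subpop), -(-n // config.n_subpop))[:n]
    freqs = _balding_nichols_freqs(rng, m, config.n_subpop, config.fst,
                                   config.maf_range)
    dosages = rng.binomial(2, freqs[subpop, :]).astype(float)

    # causal SNP: a polymorphic column with workable frequency
    p_obs = dosages.mean(axis=0) / 2.0
    eligible = np.flatnonzero((p_obs > 0.1) & (p_obs < 0.9))
    if eligible.size == 0:
        eligible = np.flatnonzero((p_obs > 0.0) & (p_obs < 1.0))
    causal = int(rng.choice(eligible))

    sigma2_e = 1.0 - config.h2_snp - config.h2_poly
    x = dosages[:, causal]
    var_x = x.var()
    if config.h2_snp > 0.0 and var_x > 0.0:
        beta = math.sqrt(config.h2_snp / var_x)
    else:
        beta = 0.0

    u = np.zeros(n)
    if config.h2_poly > 0.0:
        from .assoc import kinship, impute_missing
        K = kinship(GenotypePanel(dosages, [str(i) for i in range(n)],
                                  pd.DataFrame({"chrom": ["1"] * m,
                                                "pos": np.arange(1, m + 1),
                                                "id": [f"s{j}" for j in range(m)],
                                                "ref": ["A"] * m,
                                                "alt": ["T"] * m})))
        L = np.linalg.cholesky(K + 1e-6 * np.eye(n))
        u = math.sqrt(config.h2_poly) * (L @ rng.standard_normal(n))
        u = u / max(u.std(), 1e-12) * math.sqrt(config.h2_poly)
    e = rng.normal(0.0, math.sqrt(sigma2_e), size=n)
    y = beta * (x - x.mean()) + u + e

    if config.missing_rate > 0.0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages = dosages.copy()
        dosages[mask] = np.nan

    markers = pd.DataFrame({
        "chrom": ["1"] * m,
        "pos": np.arange(1, m + 1) * 100,
        "id": [f"snp{j:06d}" for j in range(m)],
        "ref": ["A"] * m,
        "alt": ["T"] * m,
    })
    panel = GenotypePanel(dosages, [f"acc{i:04d}" for i in range(n)], markers)
    truth = {
        "causal_index": causal if beta != 0.0 else None,
        "causal_id": markers["id"][causal] if beta != 0.0 else "null",
        "beta": beta,
        "sigma2_g": config.h2_poly,
        "sigma2_e": sigma2_e,
        "h2_snp": config.h2_snp,
        "subpop": subpop.tolist(),
    }
    return panel, y, truth
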