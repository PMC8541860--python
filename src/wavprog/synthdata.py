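"""Synthetic multi-omics cohorts with known ground truth.

Emulates the statistical structure of a paired tumor/normal bulk cohort:
log-normal expression counts with a planted differentially-expressed gene
set, beta-distributed methylation with planted differential probes that map
into the DE set with a configurable overlap, and right-censored exponential
survival whose log-hazard is linear in a planted prognostic subset of the DE
genes.  Every downstream stage of the pipeline is therefore testable against
planted truth without any external download.

Defaults describe the reference study condition used throughout the test
suite: 300 tumor / 30 normal samples, 2000 genes, five prognostic genes with
log-hazard coefficients of magnitude 0.6-0.8 per standard deviation of
log-expression, 20% independent censoring, and a 40-month mean baseline
survival so that both the 36- and 60-month evaluation horizons are well
populated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "write_cohort"]


class ConfigError(ValueError):
    """A cohort configuration field violates its constraint."""


@dataclass(frozen=True)
class CohortConfig:
    n_tumor: int = 300
    n_normal: int = 30
    n_genes: int = 2000
    n_probes: int = 4000
    n_deg: int = 250
    n_dmp: int = 300
    n_prognostic: int = 5
    effect_logfc: float = 3.0        # mean |log2 FC| of planted DEGs
    effect_deltabeta: float = 0.3    # mean |delta beta| of planted DMPs
    #: fraction of planted DMPs whose probe maps into the planted DEG set
    dmp_deg_overlap: float = 0.8
    prognostic_beta: tuple[float, ...] = (0.8, -0.8, 0.7, -0.7, 0.6)
    censor_frac: float = 0.2
    baseline_hazard: float = 1.0 / 40.0   # per month
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_normal", "n_genes", "n_probes",
                     "n_deg", "n_dmp", "n_prognostic"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_deg > self.n_genes:
            raise ConfigError("n_deg exceeds n_genes")
        if self.n_prognostic > self.n_deg:
            raise ConfigError("n_prognostic exceeds n_deg")
        if self.n_dmp > self.n_probes:
            raise ConfigError("n_dmp exceeds n_probes")
        if not 0 <= self.censor_frac < 1:
            raise ConfigError("censor_frac must lie in [0, 1)")
        if not 0 <= self.effect_deltabeta < 1:
            raise ConfigError("effect_deltabeta must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        if not 0 <= self.dmp_deg_overlap <= 1:
            raise ConfigError("dmp_deg_overlap must lie in [0, 1]")
        if len(self.prognostic_beta) != self.n_prognostic:
            raise ConfigError("prognostic_beta length must equal n_prognostic")


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame      # genes x samples
    methylation: pd.DataFrame     # probes x samples, values in [0, 1]
    probe_map: pd.DataFrame       # columns: probe, gene
    clinical: pd.DataFrame        # index samples; group, time_months, event
    truth: dict                   # planted deg / dmp / prognostic ids + betas

    def __post_init__(self) -> None:
        n = self.expression.shape[1]
        if self.methylation.shape[1] != n or len(self.clinical) != n:
            raise ValueError("expression, methylation and clinical sample counts differ")
        meth = self.methylation.to_numpy()
        if meth.min() < 0 or meth.max() > 1:
            raise ValueError("methylation beta values must lie in [0, 1]")
        if (self.clinical["time_months"] <= 0).any():
            raise ValueError("survival times must be positive")
        if not set(self.clinical["event"].unique()) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")


def _censoring_rate(hazards: np.ndarray, censor_frac: float) -> float:
    """Exponential censoring rate achieving the target expected censored fraction.

    With event time T_i ~ Exp(h_i) and independent C ~ Exp(c),
    P(C < T_i) = c / (c + h_i); solve mean_i c/(c+h_i) = censor_frac.
    """
    if censor_frac == 0:
        return 0.0
    lo = hazards.min() * 1e-9
    hi = hazards.max() * 1e9
    return brentq(
        lambda c: np.mean(c / (c + hazards)) - censor_frac, lo, hi, xtol=1e-12
    )


def generate_cohort(
    config: CohortConfig, noise_seed: int | None = None
) -> SyntheticCohort:
    """Draw one cohort; bitwise-reproducible from ``config.seed``.

    ``config.seed`` fixes the cohort's structure — which genes/probes are
    planted, effect directions, per-feature baselines and the probe map.
    ``noise_seed`` (default: derived from ``config.seed``) drives only the
    per-sample sampling noise, so two cohorts with the same config but
    different noise seeds share their ground truth and act as independent
    training/validation draws of the same population.
    """
    rng = np.random.default_rng(config.seed)
    rng_noise = np.random.default_rng(
        config.seed + 1_000_003 if noise_seed is None else noise_seed
    )
    n_samples = config.n_tumor + config.n_normal
    genes = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    probes = np.array([f"P{i:06d}" for i in range(config.n_probes)])
    samples = np.array(
        [f"T{i:04d}" for i in range(config.n_tumor)]
        + [f"N{i:04d}" for i in range(config.n_normal)]
    )
    is_tumor = np.zeros(n_samples, bool)
    is_tumor[: config.n_tumor] = True

    # --- expression: log-normal counts around gene baselines -----------------
    # planted genes are scattered over the matrix, as in a real cohort where
    # row order carries no biology
    deg_pos = np.sort(rng.choice(config.n_genes, size=config.n_deg, replace=False))
    deg_ids = genes[deg_pos]
    prog_pos = deg_pos[
        np.sort(rng.choice(config.n_deg, size=config.n_prognostic, replace=False))
    ]
    prog_ids = genes[prog_pos]
    base_log2 = rng.uniform(3.0, 8.0, size=config.n_genes)
    deg_sign = np.where(rng.random(config.n_deg) < 0.5, 1.0, -1.0)
    shift = np.zeros((config.n_genes, n_samples))
    shift[np.ix_(deg_pos, is_tumor)] = (deg_sign * config.effect_logfc)[:, None]
    log2_expr = base_log2[:, None] + shift + rng_noise.normal(
        0.0, 0.5, (config.n_genes, n_samples)
    )
    expression = pd.DataFrame(2.0**log2_expr, index=genes, columns=samples)

    # --- methylation: beta values, planted group shift -----------------------
    dmp_ids = probes[: config.n_dmp]
    probe_mean = rng.uniform(0.2, 0.8, size=config.n_probes)
    dmp_sign = np.where(rng.random(config.n_dmp) < 0.5, 1.0, -1.0)
    mean_mat = np.tile(probe_mean[:, None], (1, n_samples))
    shifted = np.clip(
        probe_mean[: config.n_dmp] + dmp_sign * config.effect_deltabeta, 0.02, 0.98
    )
    mean_mat[: config.n_dmp][:, is_tumor] = shifted[:, None]
    conc = 50.0
    methylation = pd.DataFrame(
        rng_noise.beta(mean_mat * conc, (1 - mean_mat) * conc),
        index=probes,
        columns=samples,
    )

    # --- probe -> gene map ----------------------------------------------------
    n_overlap = int(round(config.dmp_deg_overlap * config.n_dmp))
    # planted prognostic genes always receive a planted DMP so that the
    # key-gene intersection provably contains the prognostic signal
    non_prog = deg_ids[~np.isin(deg_ids, prog_ids)]
    deg_targets = np.concatenate([prog_ids, rng.permutation(non_prog)])
    mapped = []
    non_deg_pool = genes[~np.isin(genes, deg_ids)]
    for i in range(config.n_dmp):
        if i < n_overlap:
            mapped.append(deg_targets[i % len(deg_targets)])
        else:
            mapped.append(non_deg_pool[rng.integers(len(non_deg_pool))])
    for _ in range(config.n_probes - config.n_dmp):
        mapped.append(genes[rng.integers(config.n_genes)])
    probe_map = pd.DataFrame({"probe": probes, "gene": mapped})

    # --- survival: exponential, log-hazard linear in prognostic genes --------
    log2_prog = np.log2(expression.loc[prog_ids].to_numpy() + 1.0)
    tumor_block = log2_prog[:, is_tumor]
    mu = tumor_block.mean(axis=1, keepdims=True)
    sd = tumor_block.std(axis=1, keepdims=True)
    z = (log2_prog - mu) / sd
    lp = np.asarray(config.prognostic_beta) @ z
    lp[~is_tumor] = 0.0  # normals follow the baseline hazard
    hazards = config.baseline_hazard * np.exp(lp)
    t_event = rng_noise.exponential(1.0 / hazards)
    c_rate = _censoring_rate(hazards[is_tumor], config.censor_frac)
    if c_rate > 0:
        t_cens = rng_noise.exponential(1.0 / c_rate, size=n_samples)
    else:
        t_cens = np.full(n_samples, np.inf)
    time = np.maximum(np.minimum(t_event, t_cens), 0.01)
    event = (t_event <= t_cens).astype(int)
    clinical = pd.DataFrame(
        {
            "group": np.where(is_tumor, "tumor", "normal"),
            "time_months": time,
            "event": event,
        },
        index=pd.Index(samples, name="sample"),
    )

    truth = {
        "deg": deg_ids.tolist(),
        "dmp": dmp_ids.tolist(),
        "prognostic": prog_ids.tolist(),
        "prognostic_beta": list(config.prognostic_beta),
    }
    return SyntheticCohort(expression, methylation, probe_map, clinical, truth)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the TSV files consumed by the pipeline, plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "methylation": outdir / "methylation.tsv",
        "probe_map": outdir / "probe_map.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.json",
    }
    cohort.expression.to_csv(paths["expression"], sep="\t", float_format="%.4f")
    cohort.methylation.to_csv(paths["methylation"], sep="\t", float_format="%.5f")
    cohort.probe_map.to_csv(paths["probe_map"], sep="\t", index=False)
    cohort.clinical.to_csv(paths["clinical"], sep="\t", float_format="%.4f")
    paths["truth"].write_text(json.dumps(cohort.truth, indent=1))
    return paths
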