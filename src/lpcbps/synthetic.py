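"""Synthetic cohorts with a known 1-D progression structure per process.

Each biological process places tumor samples along a latent progression
coordinate u ~ Uniform(0, 1); every gene of the process is a smooth function
of u (a line, a circular arc, or a sigmoidal S-curve, with per-gene
coefficients drawn once from the seed) plus i.i.d. Gaussian noise.  Normal
samples sit at u = 0 with the same noise, so "deviation from normals" is the
latent coordinate itself.  Survival times follow an exponential model whose
log-hazard is proportional to the mean latent value of a designated subset of
driver processes; censoring comes from an independent exponential censoring
time whose rate is calibrated so the expected censored fraction equals
``censor_rate``.

The generator emulates the geometry the scoring method assumes (a connected
1-D manifold per gene set, normals clustered at one end).  It does not model
batch effects, platform noise, subtype mixtures or branched topologies.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd

from .io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    write_clinical,
    write_expression,
    write_gmt,
)

CURVE_SHAPES = ("line", "arc", "s-curve")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    #: process name -> latent u per tumor sample (tumor column order)
    latent: Dict[str, np.ndarray]
    driver_processes: List[str]
    #: tumor samples only: columns sample, time, status
    survival: ClinicalTable
    genesets: GeneSetCollection
    seed: int

    @property
    def tumor_ids(self) -> List[str]:
        return [
            s
            for s, r in zip(self.expression.sample_ids, self.expression.is_reference)
            if not r
        ]


def _gene_curve(shape: str, u: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-gene smooth mean expression as a function of latent u.

    ``a``, ``b`` are per-gene coefficient vectors; returns (genes, samples).
    """
    u = u[None, :]
    a = a[:, None]
    b = b[:, None]
    if shape == "line":
        return a + b * u
    if shape == "arc":
        # a genuinely curved 1-D manifold a linear PC cannot parameterize
        return a * np.cos(np.pi * u) + b * np.sin(np.pi * u)
    if shape == "s-curve":
        return a / (1.0 + np.exp(-10.0 * (u - 0.5))) + b * u
    raise ValueError(f"curve_shape must be one of {CURVE_SHAPES}, got {shape!r}")


def _calibrate_censoring_rate(event_rates: np.ndarray, censor_rate: float) -> float:
    """Censoring rate c with E[c / (c + rate_i)] == censor_rate over the cohort."""
    from scipy.optimize import brentq

    def gap(c):
        return float(np.mean(c / (c + event_rates))) - censor_rate

    return float(brentq(gap, 1e-12, 1e12))


def generate_cohort(
    n_tumor: int = 200,
    n_normal: int = 40,
    n_processes: int = 20,
    genes_per_process: int = 50,
    n_drivers: int = 3,
    curve_shape: str = "arc",
    noise_sd: float = 0.05,
    hazard_coef: float = 2.0,
    censor_rate: float = 0.3,
    seed: int = 0,
) -> SyntheticCohort:
    """Draw a fully reproducible synthetic cohort.

    Survival: T ~ Exponential with rate exp(hazard_coef * mean_u_drivers)
    (baseline rate 1).  An independent censoring time C ~ Exponential(c) is
    drawn per sample, with c solved so that the expected censored fraction
    E[c / (c + rate_i)] over the cohort equals ``censor_rate``; the observed
    time is min(T, C) and status = 1 iff T <= C.  Censoring is independent of
    the event process given the cohort, so observed event status carries
    (partial) information about risk, as in a real follow-up study.
    """
    if n_tumor < 10:
        raise ValueError("n_tumor must be >= 10")
    if n_normal < 0 or n_processes <= 0 or genes_per_process <= 0:
        raise ValueError("dimensions must be positive (n_normal may be 0)")
    if not 0 <= n_drivers <= n_processes:
        raise ValueError("n_drivers must be in [0, n_processes]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0.0 <= censor_rate <= 1.0:
        raise ValueError("censor_rate must be in [0, 1]")
    if curve_shape not in CURVE_SHAPES:
        raise ValueError(f"curve_shape must be one of {CURVE_SHAPES}")

    rng = np.random.default_rng(seed)
    n_samples = n_tumor + n_normal

    proc_names = [f"PROC_{p + 1:03d}" for p in range(n_processes)]
    tumor_ids = [f"T{i + 1:04d}" for i in range(n_tumor)]
    normal_ids = [f"N{i + 1:04d}" for i in range(n_normal)]
    sample_ids = tumor_ids + normal_ids
    is_reference = np.array([False] * n_tumor + [True] * n_normal)

    latent: Dict[str, np.ndarray] = {}
    blocks = []
    gene_ids: List[str] = []
    sets: Dict[str, tuple] = {}
    for p, name in enumerate(proc_names):
        u_tumor = rng.uniform(0.0, 1.0, size=n_tumor)
        u = np.concatenate([u_tumor, np.zeros(n_normal)])
        latent[name] = u_tumor
        a = rng.normal(0.0, 1.0, size=genes_per_process)
        if curve_shape == "line":
            # bounded-away-from-zero slopes keep every gene informative
            b = rng.choice([-1.0, 1.0], size=genes_per_process) * rng.uniform(
                0.5, 1.5, size=genes_per_process
            )
        else:
            b = rng.normal(0.0, 1.0, size=genes_per_process)
        mean = _gene_curve(curve_shape, u, a, b)
        noise = rng.normal(0.0, noise_sd, size=mean.shape) if noise_sd > 0 else 0.0
        blocks.append(mean + noise)
        genes = [f"{name}_G{g + 1:03d}" for g in range(genes_per_process)]
        gene_ids.extend(genes)
        sets[name] = (f"synthetic process {p + 1}", genes)

    values = np.vstack(blocks)
    expression = ExpressionMatrix(values, gene_ids, sample_ids, is_reference)
    genesets = GeneSetCollection(sets)

    drivers = sorted(
        rng.choice(proc_names, size=n_drivers, replace=False).tolist()
    )
    if drivers:
        mean_u = np.mean([latent[d] for d in drivers], axis=0)
    else:
        mean_u = np.zeros(n_tumor)
    log_hazard = hazard_coef * mean_u
    rates = np.exp(log_hazard)
    times = rng.exponential(scale=1.0 / rates)
    if censor_rate == 0.0:
        follow_up = times
        status = np.ones(n_tumor, dtype=int)
    elif censor_rate == 1.0:
        # degenerate limit: follow-up cut before every event
        follow_up = rng.uniform(size=n_tumor) * times
        status = np.zeros(n_tumor, dtype=int)
    else:
        c_rate = _calibrate_censoring_rate(rates, censor_rate)
        censor_times = rng.exponential(scale=1.0 / c_rate, size=n_tumor)
        status = (times <= censor_times).astype(int)
        follow_up = np.minimum(times, censor_times)
    follow_up = np.maximum(follow_up, 1e-12)  # keep times strictly positive
    survival = ClinicalTable(
        pd.DataFrame({"sample": tumor_ids, "time": follow_up, "status": status})
    )

    return SyntheticCohort(
        expression=expression,
        latent=latent,
        driver_processes=drivers,
        survival=survival,
        genesets=genesets,
        seed=seed,
    )


def write_cohort(cohort: SyntheticCohort, directory) -> Dict[str, str]:
    """Emit expression TSV, GMT, clinical TSV and a truth TSV (for tests)."""
    os.makedirs(directory, exist_ok=True)
    paths = {
        "expression": os.path.join(directory, "expression.tsv"),
        "gmt": os.path.join(directory, "genesets.gmt"),
        "clinical": os.path.join(directory, "clinical.tsv"),
        "truth": os.path.join(directory, "truth.tsv"),
    }
    write_expression(cohort.expression, paths["expression"])
    write_gmt(cohort.genesets, paths["gmt"])
    write_clinical(cohort.survival, paths["clinical"])
    rows = []
    tumor_ids = cohort.tumor_ids
    for name, u in cohort.latent.items():
        for s, ui in zip(tumor_ids, u):
            rows.append((s, name, ui))
    pd.DataFrame(rows, columns=["sample", "process", "latent"]).to_csv(
        paths["truth"], sep="\t", index=False
    )
    return paths
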