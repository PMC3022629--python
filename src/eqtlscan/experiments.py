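"""Calibration experiments for the association engine.

These drive the package's own coding/fitting path over simulated data to
measure its operating characteristics: type-I error under the null, bias of
the recovered effect size, and end-to-end detection of a planted eQTL.
They back the statistical checks in the test suite and the reproduction
script, and are usable as diagnostics on any install.
"""

from __future__ import annotations

import tempfile
from typing import Dict

import numpy as np

from .assoc import GeneticModel, code_genotypes, fit_wald, run_association
from .expression_io import merge_samples, read_expression_table
from .genotype_io import read_ped_map, read_sample_info
from .pipeline import RunConfig, run
from .simdata import CausalSpec, PopulationSpec, SimConfig, simulate_expression, simulate_genotypes, snp_grid, write_fixture


def _calls_from_counts(counts: np.ndarray) -> np.ndarray:
    """Allele-pair matrix with 'A' minor / 'G' major from 0/1/2 counts."""
    calls = np.empty((counts.size, 2), dtype="U8")
    calls[:, 0] = np.where(counts >= 1, "A", "G")
    calls[:, 1] = np.where(counts == 2, "A", "G")
    return calls


def type_one_error_rate(
    model: GeneticModel,
    n_tests: int = 5000,
    n: int = 100,
    maf: float = 0.3,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate at ``alpha`` when genotype and phenotype are independent.

    Each test draws fresh Hardy-Weinberg genotype counts and a fresh
    standard-normal phenotype; degenerate draws are redrawn so exactly
    ``n_tests`` valid tests contribute.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    done = 0
    while done < n_tests:
        counts = rng.binomial(2, maf, size=n)
        design = code_genotypes(_calls_from_counts(counts), model)
        if design.degenerate:
            continue
        y = rng.standard_normal(n)
        fit = fit_wald(design, y)
        rejections += fit.p < alpha
        done += 1
    return rejections / n_tests


def parameter_recovery(
    beta: float = 0.5,
    noise_sd: float = 1.0,
    n: int = 500,
    maf: float = 0.3,
    reps: int = 500,
    seed: int = 0,
) -> float:
    """Mean fitted additive beta over ``reps`` simulated single-SNP studies."""
    betas = []
    for r in range(reps):
        cfg = SimConfig(
            populations=[PopulationSpec("POP", n_unrelated=n)],
            snps=[*snp_grid(1, maf=maf)],
            causal=CausalSpec("rs1", GeneticModel.ADDITIVE, beta=beta, noise_sd=noise_sd),
            seed=seed + r,
        )
        ds = simulate_genotypes(cfg)
        profile = simulate_expression(ds, cfg)[0]
        mds, mp = merge_samples(ds, profile)
        res = run_association(mds, mp, GeneticModel.ADDITIVE)[0]
        if not res.is_degenerate:
            betas.append(res.beta)
    return float(np.mean(betas))


def causal_detection_successes(
    n_seeds: int = 50,
    n: int = 200,
    n_snps: int = 21,
    causal_snp: str = "rs11",
    beta: float = 1.0,
    noise_sd: float = 0.5,
    base_seed: int = 0,
) -> int:
    """End-to-end runs on fixtures with one planted causal SNP among nulls.

    Each seed writes a fresh PED/MAP/expression fixture, runs the full
    pipeline from disk, and scores a success when the planted SNP attains
    the minimum p in the association table.
    """
    successes = 0
    for s in range(n_seeds):
        cfg = SimConfig(
            populations=[PopulationSpec("CEU", n_unrelated=n)],
            snps=snp_grid(n_snps),
            causal=CausalSpec(causal_snp, beta=beta, noise_sd=noise_sd),
            seed=base_seed + s,
        )
        ds = simulate_genotypes(cfg)
        profiles = simulate_expression(ds, cfg)
        with tempfile.TemporaryDirectory() as td:
            paths = write_fixture(ds, profiles, td)
            rr = run(
                RunConfig(
                    gene_symbol=cfg.gene_symbol,
                    ped_path=str(paths["ped"]),
                    map_path=str(paths["map"]),
                    sample_info_path=str(paths["sample_info"]),
                    expression_path=str(paths["expression"]),
                    out_dir=td + "/out",
                    chromosome="4",
                    region=(8_100_000, 8_400_000),
                )
            )
        results = rr.probes[0].results
        best = min((r for r in results if not r.is_degenerate), key=lambda r: r.p)
        successes += best.snp_id == causal_snp
    return successes
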