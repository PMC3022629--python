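import io

import numpy as np
import pytest

import eqtlscan as eq


@pytest.fixture
def hapmap_ds():
    """270-sample, 12-SNP dataset with the HapMap phase II pedigree shape."""
    cfg = eq.SimConfig(
        populations=eq.hapmap_populations(),
        snps=eq.snp_grid(12),
        seed=11,
    )
    return eq.simulate_genotypes(cfg)


@pytest.fixture
def causal_fixture(tmp_path):
    """On-disk PED/MAP/expression fixture with a planted additive eQTL."""
    cfg = eq.SimConfig(
        populations=[eq.PopulationSpec("CEU", n_unrelated=200)],
        snps=eq.snp_grid(21),
        causal=eq.CausalSpec("rs11", beta=1.0, noise_sd=0.5),
        n_probes_per_gene=2,
        seed=5,
    )
    ds = eq.simulate_genotypes(cfg)
    profiles = eq.simulate_expression(ds, cfg)
    paths = eq.write_fixture(ds, profiles, tmp_path / "fix")
    return cfg, ds, profiles, paths


def make_ped_map(ped_text: str, map_text: str):
    """Read a PED/MAP pair given as inline strings."""
    return eq.read_ped_map(io.StringIO(ped_text), io.StringIO(map_text))


@pytest.fixture
def tiny_ds():
    """3 samples x 3 SNPs, hand-written, with one missing call."""
    map_text = "1\trs1\t0\t100\n1\trs2\t0\t200\n1\trs3\t0\t300\n"
    ped_text = (
        "F1 I1 0 0 1 -9  A A  A G  0 0\n"
        "F1 I2 0 0 2 -9  A G  G G  C C\n"
        "F2 I3 0 0 1 -9  G G  G G  C T\n"
    )
    return make_ped_map(ped_text, map_text)
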