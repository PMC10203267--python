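"""Shared fixtures: small seeded simulation configs and toy matrices."""

from __future__ import annotations

import numpy as np
import pytest

from zwscan.genotypes import GenotypeMatrix
from zwscan.synthetic_data import SimulationConfig


def make_gm(dosage, sex=None, subgroup=None, chrom=None, pos=None,
            dp=None, qual=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a (samples × sites) dosage array with
    simple defaults for everything else."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_sites = dosage.shape
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n_samples)],
        sex=np.array(sex if sex is not None else ["unknown"] * n_samples, dtype=object),
        subgroup=np.array(
            subgroup if subgroup is not None else ["other"] * n_samples, dtype=object
        ),
        chrom=np.array(chrom if chrom is not None else ["chr1"] * n_sites, dtype=object),
        pos=np.asarray(
            pos if pos is not None else np.arange(1, n_sites + 1) * 100, dtype=np.int64
        ),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        dp=np.asarray(dp if dp is not None else np.full(n_sites, 20.0), dtype=float),
        qual=np.asarray(qual if qual is not None else np.full(n_sites, 50.0), dtype=float),
        dosage=dosage,
    )


def small_zw_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A scaled-down ZW layout (5.5-Mb sex chromosome, one 2-Mb autosome)
    preserving the structure of the default study-scale configuration."""
    params = dict(
        seed=seed,
        chromosomes={"Chr14": 5_500_000, "Chr01": 2_000_000},
        zw_chromosome="Chr14",
        sdr_start=1_500_000,
        sdr_end=4_500_000,
        inversions=[
            (3_200_000, 4_300_000, 4_700_000, 5_000_000, 8.18e6, 30),
            (2_200_000, 3_100_000, 4_350_000, 4_650_000, 3.80e6, 30),
            (1_600_000, 2_100_000, 4_100_000, 4_300_000, 3.47e6, 20),
        ],
        collinear_blocks=[
            (1_500_000, 1_590_000, 3_900_000, 4_000_000, 2.0e5, 8),
            (4_310_000, 4_500_000, 5_010_000, 5_200_000, 2.0e5, 8),
        ],
        n_w_segments=4,
        w_segment_bp=300_000,
        z_elevated_bp=150_000,
        background_snp_spacing=4_000,
        sex_linked_spacing=10_000,
        subgroup_sizes={"wild": 8, "Cultivar_I": 8},
        theta={"wild": 2e-3, "Cultivar_I": 2e-3},
        sweeps=[("Chr01", 810_001, 910_000, 5.0)],
        sweep_subgroups=("Cultivar_I",),
        marker_spacing=100_000,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture
def zw_small():
    from zwscan.synthetic_data import simulate_zw_reference

    cfg = small_zw_config(seed=11)
    layout, truth = simulate_zw_reference(cfg)
    return cfg, layout, truth
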