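import dataclasses

import numpy as np
import pandas as pd
import pytest

import beltmap as bm


@pytest.fixture(scope="session")
def small_cfg() -> bm.SimConfig:
    """A fast 60-animal, 300-SNP cohort used by several suites."""
    return dataclasses.replace(
        bm.SimConfig(), n_snps=300, n_animals=60, belt_snp_index=150, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return bm.simulate_panel(small_cfg)


def truth_panel(panel, truth) -> bm.PhasedPanel:
    """The complete truth-phase panel (stands in for external phasing)."""
    return bm.PhasedPanel(panel.chrom, panel.snp_ids, panel.pos, truth.true_haps, panel.animal_ids)


def polymorphic(panel: bm.PhasedPanel) -> bm.PhasedPanel:
    from beltmap.kernels import allele_frequencies

    freq = allele_frequencies(panel.genotypes())
    return panel.subset_snps((freq > 0) & (freq < 1))


def single_animal_truth(n_carrier_haps: int, belt_bp: int = 1000) -> bm.Truth:
    """Minimal one-animal Truth for depth/qPCR simulations."""
    hap_carrier = np.zeros((1, 2), dtype=bool)
    hap_carrier[0, :n_carrier_haps] = True
    return bm.Truth(
        table=pd.DataFrame(
            {
                "animal_id": ["A1"],
                "breed": ["BGA"],
                "true_copies": [n_carrier_haps],
                "belted_true": [n_carrier_haps > 0],
                "group": ["het" if n_carrier_haps == 1 else ("likely_hom" if n_carrier_haps == 2 else "nonbelted")],
            }
        ),
        hap_carrier=hap_carrier,
        true_haps=np.zeros((1, 2, 41), dtype=np.int8),
        trios=[],
        planted_mendel=[],
        belt_snp_index=0,
        belt_bp=belt_bp,
    )
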