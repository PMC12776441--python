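import numpy as np
import pandas as pd
import pytest

from phototf.genome import GenomeSequence
from phototf.intervals import GenomicInterval, IntervalSet
from phototf.sites import BindingSiteSet
from phototf.simulate import (default_truth_tables, generate_genome, plant_sites,
                              simulate_damage, PlantedEffect)
from phototf.background import estimate_context_rates


@pytest.fixture()
def toy_genome():
    return GenomeSequence({"c1": "GATTCAGGAATTCCGGTACC", "c2": "GAATCCAGTT"})


@pytest.fixture(scope="session")
def sim_cluster():
    """A medium synthetic cluster with one planted formation effect.

    Consensus GGAATT occupies motif-axis positions -3..2 (G G A A T T on the
    motif strand), so the motif-strand TT dinucleotide sits at position 1
    ("1/2") and the complement-strand CC under the GG at position -3.
    The planted effect triples formation at (1, motif).
    """
    truth = default_truth_tables(11)
    g = generate_genome(1, 800 * 220 + 2000, 0.41, 1)
    g, sites, acc = plant_sites(g, "GGAATT", 800, 220, 2, score_noise=0.05)
    effect = PlantedEffect(1, "motif", "formation", 3.0)
    dmap = simulate_damage(g, acc, truth, [effect], sites, seed=3)
    rates = estimate_context_rates(dmap, g, acc, k_flank=2)
    return {"truth": truth, "genome": g, "sites": sites, "accessible": acc,
            "damage": dmap, "rates": rates, "effect": effect}
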