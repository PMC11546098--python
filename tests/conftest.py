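import numpy as np
import pytest

from dendrogwas import synth
from dendrogwas.core import Chronology, GenotypeMatrix, IndexSeries, RingSeries


@pytest.fixture
def small_cfg():
    """Three small populations, enough SNPs for LD structure."""
    return synth.SimConfig(
        n_pops=3, n_trees_per_pop=[20, 20, 20], n_snps=300,
        n_causal=2, seed=11,
    )


@pytest.fixture
def small_sim(small_cfg):
    g, truth = synth.simulate_genotypes(small_cfg)
    return g, truth


def make_ring_series(tree_id="t1", start=1900, widths=None, n=100, value=1.0):
    if widths is None:
        widths = np.full(n, value)
    widths = np.asarray(widths, float)
    return RingSeries(tree_id, np.arange(start, start + len(widths)), widths)


def make_index_series(tree_id="t1", start=1900, indices=None, n=100):
    if indices is None:
        indices = np.ones(n)
    indices = np.asarray(indices, float)
    return IndexSeries(tree_id, np.arange(start, start + len(indices)), indices)


def make_genotypes(calls, pops=None, groups=None):
    calls = np.asarray(calls, dtype=np.int8)
    n = calls.shape[0]
    if pops is None:
        pops = ["p1"] * n
    return GenotypeMatrix(calls, [f"t{i}" for i in range(n)], list(pops), groups)


def deterministic_episode_construction(n_affected=9, start=1972, duration=3,
                                       depress=0.6):
    """Fully deterministic host/nonhost pair: alternating +/-0.01 background
    (in phase between host and nonhost, with the episode's neighbours above
    zero) plus a flat depression.  Runs cannot extend by chance, so the
    min-duration rule is exact."""
    years = np.arange(1930, 2010)
    alt = 0.01 * np.where(np.arange(len(years)) % 2 == 1, 1, -1)
    host = []
    for i in range(30):
        idx = 1.0 + alt.copy()
        if i < n_affected:
            mask = (years >= start) & (years <= start + duration - 1)
            idx[mask] = depress
        host.append(IndexSeries(f"t{i}", years, idx))
    nonhost = Chronology(years, 1.0 + alt, np.full(len(years), 20))
    return host, nonhost


@pytest.fixture
def defol_host_factory():
    """Direct index-level construction: 30 trees, optional depressed subset.

    The depression follows the documented outbreak shape: onset buffered,
    maximum decline (x0.6) 1-2 years after onset, slow partial recovery.
    """

    def build(seed, n_affected=9, start=1972, duration=6, noise=0.05,
              flat_depress=None):
        rng = np.random.default_rng(seed)
        years = np.arange(1930, 2010)
        profile = {0: 0.75, 1: 0.6, 2: 0.6, 3: 0.7, 4: 0.8, 5: 0.85}
        # common climate-like signal shared by host trees and tracked by the
        # non-host chronology (as in real host/non-host pairs)
        common = rng.normal(0, 0.05, len(years))
        host = []
        for i in range(30):
            idx = 1.0 + common + rng.normal(0, noise, len(years))
            if i < n_affected:
                for off in range(duration):
                    y = start + off
                    m = flat_depress if flat_depress is not None else profile.get(off, 0.85)
                    idx[y - 1930] *= m
            host.append(IndexSeries(f"t{i}", years, idx))
        nonhost = Chronology(
            years, 1.0 + common + rng.normal(0, 0.01, len(years)),
            np.full(len(years), 20)
        )
        return host, nonhost

    return build
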