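"""Shared fixtures: the seeded reference cohort and derived pipeline stages.

The heavy objects (cohort, per-stratum association tables, networks,
partitions, a full pipeline run) are session-scoped so the whole suite
pays for them once.
"""

import warnings

import networkx as nx
import numpy as np
import pytest

import morbinet as mn
from morbinet import synthetic_data as sd
from morbinet.cli_io import RunConfig, run_all

COHORT_SEED = 7
PARTITION_SEED = 99


@pytest.fixture(scope="session")
def default_cohort():
    """Reference cohort: matrices, truth labels and summaries."""
    cfg = sd.default_config(seed=COHORT_SEED)
    mats, truth = sd.generate_cohort(cfg)
    summaries = [sd.summarize(m) for m in mats]
    return cfg, mats, truth, summaries


@pytest.fixture(scope="session")
def cohort_networks(default_cohort):
    """Association records, vigintile thresholds and signed networks."""
    cfg, mats, truth, summaries = default_cohort
    catalog = sd.make_catalog(cfg)
    records, thresholds, nets = {}, {}, {}
    for s in summaries:
        recs = mn.build_association_table(s)
        thr = mn.vigintile_thresholds(recs)
        records[s.stratum] = recs
        thresholds[s.stratum] = thr
        nets[s.stratum] = mn.build_signed_network(recs, thr, catalog=catalog)
    return records, thresholds, nets


@pytest.fixture(scope="session")
def cohort_partitions(default_cohort, cohort_networks):
    """Spin-glass partitions at estimated resolution, one per stratum."""
    cfg, mats, truth, summaries = default_cohort
    _, _, nets = cohort_networks
    ss = np.random.SeedSequence(PARTITION_SEED).spawn(2 * len(summaries))
    parts = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, s in enumerate(summaries):
            net = nets[s.stratum]
            gammas = mn.estimate_gammas(net, max_rounds=6, seed=ss[2 * k])
            parts[s.stratum] = mn.spinglass_partition(
                net, gammas=gammas, seed=ss[2 * k + 1], n_spins=45
            )
    return parts


@pytest.fixture(scope="session")
def null_run(tmp_path_factory):
    """Two identical scaled-down pipeline runs (structure-free cohort)."""
    base = tmp_path_factory.mktemp("runs")
    outs = []
    for name in ("a", "b"):
        config = RunConfig(
            seed=5,
            out_dir=str(base / name),
            generator_preset="null",
            n_perm=99,
            n_random=99,
            small_world_samples=20,
            annealing_schedule=(1.0, 0.05, 0.97, 20),
            gamma_rounds=2,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            manifest = run_all(config)
        outs.append((base / name, manifest))
    return outs


@pytest.fixture
def make_net():
    """Factory: SignedNetwork from (u, v, rr) triples."""

    def _make(edges, stratum=("19-24", "men")):
        g = nx.Graph()
        for u, v, rr in edges:
            g.add_edge(u, v, weight=mn.signed_weight(rr), rr=rr)
        return mn.SignedNetwork(stratum, g)

    return _make
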