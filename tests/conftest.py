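import numpy as np
import pytest

import orthosplice as osp
from orthosplice.search import SearchParams, build_seed_index, search_nucleotide


def mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    from orthosplice.simulate import mutate_sequence

    return mutate_sequence(seq, divergence, rng)


@pytest.fixture(scope="session")
def fixture_run():
    """The packaged two-species study fixture with its RBH analysis, run
    once per session (default config: 100 genes, divergence 0.13, 20%
    conserved, 10% loss, 5% duplication, seed 7)."""
    models, ta, tb, truth = osp.study_fixture()
    params = SearchParams()
    hits_ab = search_nucleotide(ta, build_seed_index(tb, params), params)
    hits_ba = search_nucleotide(tb, build_seed_index(ta, params), params)
    pairs = osp.reciprocal_best_hits(hits_ab, hits_ba, a_class=truth.a_class)
    return {
        "models": models, "transcripts_a": ta, "transcripts_b": tb,
        "truth": truth, "hits_ab": hits_ab, "hits_ba": hits_ba,
        "pairs": pairs, "params": params,
    }


@pytest.fixture(scope="session")
def lyase_analog():
    """Single-locus, 8-intron isogroup with retention 0.5 (the extreme
    intron-retention scenario), 40 isotigs for unit-level checks."""
    from orthosplice.simulate import (SimulationConfig, generate_gene_models,
                                      generate_splice_isoforms)

    cfg = SimulationConfig(n_genes=1, exon_count_range=(9, 9),
                           exon_len_range=(80, 160), intron_len_range=(60, 120),
                           retention_prob=0.5, n_isotigs_per_isogroup=40,
                           seed=11)
    model = generate_gene_models(cfg)[0]
    isotigs, gid, struth, warnings = generate_splice_isoforms(model, cfg)
    return cfg, model, isotigs, gid, struth
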