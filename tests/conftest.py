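"""Shared fixtures: small simulated experiments reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from shuffleseq.config import Config
from shuffleseq.simulate import (DEFAULT_DESIGN, SimState, apply_cre_events,
                                 emit_ivt_reads, place_insertions,
                                 simulate_reference)


@pytest.fixture()
def cfg() -> Config:
    return Config(seed=0)


@pytest.fixture(scope="session")
def tiny_genome():
    return simulate_reference({"chr1": 150_000, "chr2": 150_000},
                              variant_spacing=150.0, seed=7)


@pytest.fixture(scope="session")
def small_state(tiny_genome) -> SimState:
    """4 clones × 8 insertions with recombination events."""
    insertions = place_insertions(tiny_genome, 4, 8, seed=1)
    state = SimState(DEFAULT_DESIGN, tiny_genome, insertions, seed=0)
    state.events, state.derivatives = apply_cre_events(
        insertions, rate=10.0, cis_decay_lambda=30_000.0, trans_rate=0.2,
        seed=2)
    return state


@pytest.fixture(scope="session")
def small_ivt_obs(small_state):
    """Error-free IVT observations for the small experiment."""
    from shuffleseq.insertion_mapping import observations_from_reads
    reads = emit_ivt_reads(small_state, depth_per_side=8, read_len=120,
                           err_rate=0.0, seed=3)
    obs, drops = observations_from_reads(reads, small_state.genome)
    return obs, drops, reads


@pytest.fixture(scope="session")
def sc_experiment():
    """Clonotype-scale experiment: 20 clones, 2,000 cells, capture 0.7,
    ambient 2%, doublets 3% — with clonotypes and assignments computed."""
    from shuffleseq.simulate import emit_t7_single_cell_reads
    from shuffleseq.singlecell import (iterate_rounds, jaccard,
                                       matrix_from_records, qc_cells)

    cfg = Config(seed=0)
    genome = simulate_reference({"chr1": 600_000, "chr2": 600_000},
                                variant_spacing=150.0, seed=7)
    insertions = place_insertions(genome, 20, 30, seed=1)
    state = SimState(DEFAULT_DESIGN, genome, insertions, seed=0)
    state.events, state.derivatives = apply_cre_events(
        insertions, rate=3.0, cis_decay_lambda=150_000.0, trans_rate=0.1,
        seed=2)
    records, cell_truth, qc, whitelist = emit_t7_single_cell_reads(
        state, n_cells=2000, capture_rate=0.7, umi_depth=cfg.sc_umi_depth,
        ambient_rate=0.02, doublet_rate=0.03, seed=3)
    retained = qc_cells(qc, cfg.qc_min_umi, cfg.qc_mito_range,
                        cfg.qc_doublet_max)
    matrix = matrix_from_records(records, cfg, retained)
    clonotypes, assignments = iterate_rounds(matrix, cfg)
    clone_pairs = {c: frozenset(zip(s["bc1"], s["bc2"]))
                   for c, s in insertions.groupby("clone_id")}
    best_match = {c.id: max((jaccard(c.barcode_pairs, p), name)
                            for name, p in clone_pairs.items())
                  for c in clonotypes}
    return {
        "config": cfg, "state": state, "records": records,
        "cell_truth": cell_truth, "qc": qc, "whitelist": whitelist,
        "matrix": matrix, "clonotypes": clonotypes,
        "assignments": assignments, "clone_pairs": clone_pairs,
        "best_match": best_match,
    }


@pytest.fixture(scope="session")
def big_experiment():
    """Parameter-recovery experiment at the study's stated scale: 100
    clones x 50 insertions, IVT depth 10/side at 0.1% error, deep parental
    amplicons, post-Cre amplicons for ~500 recombination events."""
    from shuffleseq.bulk_svcalls import (average_parental_replicates,
                                         call_rearrangements,
                                         count_amplicon_pairs)
    from shuffleseq.insertion_mapping import (map_insertions,
                                              observations_from_reads,
                                              ReadPlacer)
    from shuffleseq.simulate import (emit_amplicon_reads, emit_ivt_reads,
                                     parental_cassettes, post_cre_cassettes)

    cfg = Config(seed=0)
    state = __import__("shuffleseq").simulate_experiment(cfg)
    placer = ReadPlacer(state.genome)
    obs_reps = []
    for rep in (1, 2):
        reads = emit_ivt_reads(state, depth_per_side=cfg.ivt_depth_per_side,
                               read_len=cfg.ivt_read_len,
                               err_rate=cfg.ivt_err_rate,
                               seed=cfg.seed + 10 + rep)
        obs, _ = observations_from_reads(reads, state.genome, placer=placer)
        obs_reps.append(obs)
    amp_reps = [count_amplicon_pairs(emit_amplicon_reads(
        parental_cassettes(state), cfg.amplicon_dialect,
        cfg.molecules_per_cassette, cfg.umis_per_molecule,
        chimera_rate=0.0, seed=cfg.seed + 30 + r))
        for r in range(1, 5)]
    support = average_parental_replicates(amp_reps, cfg.cpm_scale)
    mapping = map_insertions(obs_reps, cfg, support)
    post_reads = emit_amplicon_reads(
        post_cre_cassettes(state), cfg.amplicon_dialect,
        cfg.molecules_per_cassette, cfg.umis_per_molecule,
        chimera_rate=0.0, seed=cfg.seed + 41)
    calls = call_rearrangements(count_amplicon_pairs(post_reads),
                                mapping.insertions,
                                cfg.rearrangement_min_umi).calls
    control_reads = emit_amplicon_reads(
        parental_cassettes(state), cfg.amplicon_dialect,
        cfg.molecules_per_cassette, cfg.umis_per_molecule,
        chimera_rate=0.0, seed=cfg.seed + 42)
    control_calls = call_rearrangements(count_amplicon_pairs(control_reads),
                                        mapping.insertions,
                                        cfg.rearrangement_min_umi).calls
    return {"config": cfg, "state": state, "mapping": mapping,
            "calls": calls, "control_calls": control_calls}


def fabricate_insertions(n: int, length: int, seed: int = 0,
                         chrom: str = "chr1",
                         clone_id: str = "clone0") -> pd.DataFrame:
    """Bare insertion table with synthetic positions (no genome needed)."""
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(length, n, replace=False)) + 1
    return pd.DataFrame({
        "insertion_id": [f"fab{i:05d}" for i in range(n)],
        "clone_id": clone_id,
        "chrom": chrom,
        "pos": pos,
        "orientation": np.where(rng.random(n) < 0.5, "top-CS2", "bottom-CS1"),
        "allele": np.where(rng.random(n) < 0.5, "BL6", "CAST"),
        "bc1": [_base4_barcode(i, "AAAAAAAAGG") for i in range(n)],
        "bc2": [_base4_barcode(i, "TTTTTTTTCC") for i in range(n)],
    })


def _base4_barcode(i: int, prefix: str, length: int = 20) -> str:
    digits = []
    x = i
    for _ in range(length - len(prefix)):
        digits.append("ACGT"[x % 4])
        x //= 4
    return prefix + "".join(digits)
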