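"""Hand-crafted features, interaction graphs and graph-kernel vectors."""

import subprocess
import sys
import textwrap

import networkx as nx
import numpy as np
import pytest

from rriclass.config import Config
from rriclass.duplex import Duplex, PredictionInstance
from rriclass.features import (
    build_interaction_graph,
    featurize_instances,
    gc_content,
    handcrafted_features,
    nspdk_features,
    sequence_complexity,
)
from rriclass.intervals import GenomicInterval

from oracles import recompute_features


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,value", [("GCGC", 1.0), ("AUAU", 0.0), ("GAUC", 0.5)]
    )
    def test_examples(self, seq, value):
        assert gc_content(seq) == value

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            gc_content("")


class TestComplexity:
    def test_homopolymer_is_zero(self):
        assert sequence_complexity("AAAA", 1) == 0.0

    def test_uniform_four_letters(self):
        assert sequence_complexity("ACGU", 1) == pytest.approx(2.0)

    def test_dinucleotide_tally(self):
        # ACACAC: 2-mers {AC:3, CA:2}
        want = -(3 / 5) * np.log2(3 / 5) - (2 / 5) * np.log2(2 / 5)
        assert sequence_complexity("ACACAC", 2) == pytest.approx(want)
        assert sequence_complexity("ACACAC", 2) == pytest.approx(0.971, abs=1e-3)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            sequence_complexity("A", 2)


def instance_with(pairs, energy, seq1, seq2, core1=None, core2=None, seed=(0, 5)):
    n1, n2 = len(seq1), len(seq2)
    return PredictionInstance(
        instance_id="x::pos",
        window1=GenomicInterval("chr1", 0, n1, "+"),
        window2=GenomicInterval("chr2", 0, n2, "+"),
        seq1=seq1,
        seq2=seq2,
        core1=core1 or (0, n1),
        core2=core2 or (0, n2),
        mask1=np.zeros(n1, bool),
        mask2=np.zeros(n2, bool),
        duplexes=[Duplex(pairs=pairs, energy=energy, seed=seed, rank=1)],
        polarity="positive",
    )


class TestHandcrafted:
    def test_pure_gc_helix_normalisations(self):
        pairs = tuple((t, 4 - t) for t in range(5))
        inst = instance_with(pairs, -10.0, "GGGGG", "CCCCC")
        f = handcrafted_features(inst)
        assert f["E_min"] == -10.0
        assert f["bp_total"] == 5 and f["bp_gc"] == 5
        assert f["E_per_len"] == -10.0 / 10
        assert f["E_per_gc"] == -2.0
        assert f["gc_zero"] == 0.0

    def test_gc_free_duplex_guards_division(self):
        pairs = tuple((t, 4 - t) for t in range(5))
        inst = instance_with(pairs, -5.0, "AAAAA", "UUUUU")
        f = handcrafted_features(inst)
        assert f["E_per_gc"] == 0.0 and f["gc_zero"] == 1.0

    def test_no_duplexes_returns_none(self):
        inst = instance_with(tuple((t, 4 - t) for t in range(5)), -10.0, "GGGGG", "CCCCC")
        inst.duplexes = []
        assert handcrafted_features(inst) is None

    def test_matches_independent_recomputation_on_fixture(self, small_pipeline):
        _, _, instances, _ = small_pipeline
        checked = 0
        for inst in instances:
            if not inst.duplexes:
                continue
            ours = handcrafted_features(inst)
            want = recompute_features(inst)
            assert set(ours) == set(want)
            for name in want:
                assert ours[name] == pytest.approx(want[name]), name
            checked += 1
        assert checked >= 20


class TestInteractionGraph:
    def test_gapless_three_pair_graph_counts(self):
        pairs = ((0, 2), (1, 1), (2, 0))
        inst = instance_with(pairs, -6.0, "GGG", "CCC", seed=(0, 3))
        g = build_interaction_graph(inst)
        labels = [d["label"] for _, _, d in g.edges(data=True)]
        assert g.number_of_nodes() == 6
        assert labels.count("b") == 4 and labels.count("p") == 3

    def test_duplicate_duplexes_do_not_duplicate_edges(self):
        pairs = ((0, 2), (1, 1), (2, 0))
        inst = instance_with(pairs, -6.0, "GGG", "CCC", seed=(0, 3))
        single = build_interaction_graph(inst)
        inst.duplexes.append(
            Duplex(pairs=pairs, energy=-6.0, seed=(0, 3), rank=2)
        )
        double = build_interaction_graph(inst)
        assert nx.utils.graphs_equal(single, double)

    def test_union_of_two_duplexes(self):
        d1 = ((0, 2), (1, 1))
        d2 = ((1, 1), (2, 0))
        inst = instance_with(d1, -4.0, "GGG", "CCC", seed=(0, 2))
        inst.duplexes.append(Duplex(pairs=d2, energy=-4.0, seed=(0, 2), rank=2))
        g = build_interaction_graph(inst)
        p_edges = {
            tuple(sorted((u, v)))
            for u, v, d in g.edges(data=True)
            if d["label"] == "p"
        }
        want = {tuple(sorted((("a", i), ("b", j)))) for i, j in set(d1) | set(d2)}
        assert p_edges == want


def labelled_path(labels, edge="b"):
    g = nx.Graph()
    for k, lab in enumerate(labels):
        g.add_node(k, label=lab)
    for k in range(len(labels) - 1):
        g.add_edge(k, k + 1, label=edge)
    return g


class TestNspdk:
    def test_single_node_single_feature(self):
        g = nx.Graph()
        g.add_node(0, label="A")
        v = nspdk_features(g, radius=0, distance=0, hash_bits=8)
        assert v.nnz == 1 and v.data[0] == 1.0

    def test_isomorphism_invariance_under_relabelling(self, rng):
        g = labelled_path(list("ACGUCG"))
        perm = rng.permutation(6).tolist()
        h = nx.relabel_nodes(g, {i: f"n{perm[i]}" for i in range(6)})
        a = nspdk_features(g, 2, 4, 12)
        b = nspdk_features(h, 2, 4, 12)
        assert (a != b).nnz == 0

    def test_l2_normalised(self):
        g = labelled_path(list("ACGAC"))
        v = nspdk_features(g, 2, 4, 12)
        assert np.linalg.norm(v.data) == pytest.approx(1.0)

    def test_path_acg_tuple_count(self):
        # hand enumeration for the path A-C-G, r<=1, d<=2: unordered node
        # pairs (0,0) (1,1) (2,2) (0,1) (1,2) (0,2) x 2 radii = 12 tuples
        g = labelled_path(list("ACG"))
        v = nspdk_features(g, 1, 2, 16)
        counts = v.data / v.data.min()  # at least one cell holds count 1
        assert np.allclose(counts, np.round(counts))
        assert int(np.round(counts).sum()) == 12
        assert v.nnz <= 12

    def test_byte_stable_across_processes(self):
        code = textwrap.dedent(
            """
            import networkx as nx
            from rriclass.features import nspdk_features
            g = nx.Graph()
            for k, lab in enumerate("ACGUCGA"):
                g.add_node(k, label=lab)
            for k in range(6):
                g.add_edge(k, k + 1, label="b")
            g.add_edge(0, 6, label="p")
            v = nspdk_features(g, 2, 4, 16)
            print(repr(list(zip(v.indices.tolist(), v.data.tolist()))))
            """
        )
        outs = {
            subprocess.run(
                [sys.executable, "-c", code], capture_output=True, text=True
            ).stdout
            for _ in range(2)
        }
        assert len(outs) == 1 and "[" in outs.pop()


class TestFeatureTable:
    def test_stable_columns_labels_and_na(self, small_pipeline):
        _, _, instances, table = small_pipeline
        assert table.dense.columns.is_monotonic_increasing
        assert set(np.unique(table.labels)) <= {0.0, 1.0}
        assert np.isfinite(table.dense.to_numpy()).all()
        n_with = sum(1 for i in instances if i.duplexes)
        assert len(table.ids) == n_with
        assert len(table.na_ids) == len(instances) - n_with

    def test_roundtrip_via_files(self, small_pipeline, tmp_path):
        *_, table = small_pipeline
        dense, sparse = tmp_path / "d.tsv", tmp_path / "s.tsv"
        table.write(dense, sparse)
        back = type(table).read(dense, sparse)
        assert back.ids == table.ids
        assert back.feature_names == table.feature_names
        assert np.allclose(back.dense.to_numpy(), table.dense.to_numpy())
        assert (back.sparse.indices == table.sparse.indices).all()
        assert np.allclose(back.sparse.data, table.sparse.data, atol=1e-9)
        assert back.fingerprint == table.fingerprint
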