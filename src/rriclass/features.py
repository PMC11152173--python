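"""Feature engineering for prediction instances.

Two blocks per instance:

* *hand-crafted* interaction/sequence features over the instance's duplex
  set — interaction strength (min/mean energy), duplex counts, base-pair
  composition and geometry of the most stable duplex, energies normalised
  by length / GC-pair count / pair count, and per-side sequence
  composition and complexity of both the duplex-covered subsequences and
  the site cores;
* optional *graph-kernel* features: all predicted base-pairing patterns
  of a site are merged into one labelled graph (nucleotide-labelled
  nodes, backbone 'b' and base-pair 'p' edges) and neighborhood-pair
  features are extracted at bounded shortest-path distance, with rooted
  neighborhoods canonicalised by Weisfeiler–Lehman label refinement and
  hashed into a fixed-width sparse block (L2-normalised per graph,
  deterministic across processes).

Instances without any duplex yield no feature row and are flagged for NA
reporting downstream.
"""

from __future__ import annotations

import hashlib
import math
from collections import Counter, deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import Config
from .duplex import Duplex, PredictionInstance, pair_type


def gc_content(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def sequence_complexity(seq: str, k: int) -> float:
    """Shannon entropy (bits) of the overlapping k-mer distribution."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    counts = Counter(seq[i : i + k] for i in range(len(seq) - k + 1))
    total = sum(counts.values())
    return -sum(
        (c / total) * math.log2(c / total) for c in counts.values()
    )


def _safe_complexity(seq: str, k: int) -> float:
    return sequence_complexity(seq, k) if len(seq) >= k else 0.0


def _side_sequence_features(prefix: str, seq: str) -> dict:
    feats = {
        f"gc_{prefix}": gc_content(seq),
        f"complexity1_{prefix}": _safe_complexity(seq, 1),
        f"complexity2_{prefix}": _safe_complexity(seq, 2),
    }
    for nt in "ACGU":
        feats[f"frac_{nt}_{prefix}"] = seq.count(nt) / len(seq)
    return feats


def handcrafted_features(instance: PredictionInstance) -> dict | None:
    """Named dense feature map of one instance; None when it has no
    duplex (reported NA downstream)."""
    if not instance.duplexes:
        return None
    energies = [d.energy for d in instance.duplexes]
    mfe = instance.duplexes[0]

    pair_counts = Counter(
        pair_type(instance.seq1[i], instance.seq2[j]) for i, j in mfe.pairs
    )
    span1, span2 = mfe.span1(), mfe.span2()
    len1 = span1[1] - span1[0]
    len2 = span2[1] - span2[0]
    unpaired = 0
    max_stack = stack = 1
    for t in range(1, len(mfe.pairs)):
        i, j = mfe.pairs[t]
        pi, pj = mfe.pairs[t - 1]
        g1, g2 = i - pi - 1, pj - j - 1
        unpaired += g1 + g2
        stack = stack + 1 if (g1 == 0 and g2 == 0) else 1
        max_stack = max(max_stack, stack)

    e_min = min(energies)
    n_gc = pair_counts.get("GC", 0)
    feats = {
        "E_min": e_min,
        "E_mean": float(np.mean(energies)),
        "n_duplexes": float(len(energies)),
        "bp_total": float(len(mfe.pairs)),
        "len1": float(len1),
        "len2": float(len2),
        "len_sum": float(len1 + len2),
        "bp_gc": float(n_gc),
        "bp_au": float(pair_counts.get("AU", 0)),
        "bp_gu": float(pair_counts.get("GU", 0)),
        "unpaired": float(unpaired),
        "max_stack": float(max_stack),
        "seed_length": float(mfe.seed[1]),
        "E_per_len": e_min / (len1 + len2),
        "E_per_bp": e_min / len(mfe.pairs),
        "E_per_gc": e_min / n_gc if n_gc else 0.0,
        "gc_zero": 0.0 if n_gc else 1.0,
        "frac_bp_gc": n_gc / len(mfe.pairs),
        "frac_bp_au": pair_counts.get("AU", 0) / len(mfe.pairs),
        "frac_bp_gu": pair_counts.get("GU", 0) / len(mfe.pairs),
    }
    feats.update(
        _side_sequence_features("1", instance.seq1[span1[0] : span1[1]])
    )
    feats.update(
        _side_sequence_features("2", instance.seq2[span2[0] : span2[1]])
    )
    # composition over the hull of ALL suboptimal duplexes pools more
    # sequence evidence than the minimum-energy span alone
    ulo1 = min(d.span1()[0] for d in instance.duplexes)
    uhi1 = max(d.span1()[1] for d in instance.duplexes)
    ulo2 = min(d.span2()[0] for d in instance.duplexes)
    uhi2 = max(d.span2()[1] for d in instance.duplexes)
    feats["gc_union1"] = gc_content(instance.seq1[ulo1:uhi1])
    feats["gc_union2"] = gc_content(instance.seq2[ulo2:uhi2])
    feats["len_union1"] = float(uhi1 - ulo1)
    feats["len_union2"] = float(uhi2 - ulo2)
    feats["gc_joint"] = gc_content(
        instance.seq1[span1[0] : span1[1]] + instance.seq2[span2[0] : span2[1]]
    )
    feats["gc_union_joint"] = gc_content(
        instance.seq1[ulo1:uhi1] + instance.seq2[ulo2:uhi2]
    )
    core_seq1 = instance.seq1[instance.core1[0] : instance.core1[1]]
    core_seq2 = instance.seq2[instance.core2[0] : instance.core2[1]]
    for prefix, cseq in (("core1", core_seq1), ("core2", core_seq2)):
        feats[f"gc_{prefix}"] = gc_content(cseq)
        feats[f"complexity1_{prefix}"] = _safe_complexity(cseq, 1)
        feats[f"complexity2_{prefix}"] = _safe_complexity(cseq, 2)
        feats[f"len_{prefix}"] = float(len(cseq))
    return feats


# ---------------------------------------------------------------------------
# interaction graph + NSPDK-style features


def build_interaction_graph(instance: PredictionInstance) -> nx.Graph:
    """Merged base-pairing graph of all duplexes of one instance.

    Nodes are window positions inside the union span of the duplexes on
    each side (node ids ('a', pos) / ('b', pos)), labelled by nucleotide;
    backbone edges ('b') join adjacent positions, one base-pair edge
    ('p') per distinct pair across all duplexes.
    """
    if not instance.duplexes:
        raise ValueError("instance has no duplexes")
    lo1 = min(d.span1()[0] for d in instance.duplexes)
    hi1 = max(d.span1()[1] for d in instance.duplexes)
    lo2 = min(d.span2()[0] for d in instance.duplexes)
    hi2 = max(d.span2()[1] for d in instance.duplexes)
    g = nx.Graph()
    for side, lo, hi, seq in (
        ("a", lo1, hi1, instance.seq1),
        ("b", lo2, hi2, instance.seq2),
    ):
        for pos in range(lo, hi):
            g.add_node((side, pos), label=seq[pos])
        for pos in range(lo, hi - 1):
            g.add_edge((side, pos), (side, pos + 1), label="b")
    for d in instance.duplexes:
        for i, j in d.pairs:
            g.add_edge(("a", i), ("b", j), label="p")
    return g


def _stable_hash(text: str) -> str:
    return hashlib.blake2b(text.encode(), digest_size=8).hexdigest()


def _wl_labels(graph: nx.Graph, radius: int) -> list:
    """labels[r][node]: WL label after r refinement rounds (r=0: the raw
    node label), encoding the radius-r rooted neighborhood canonically."""
    current = {v: str(graph.nodes[v]["label"]) for v in graph.nodes}
    rounds = [dict(current)]
    for _ in range(radius):
        nxt = {}
        for v in graph.nodes:
            neigh = sorted(
                f"{graph.edges[v, u]['label']}:{current[u]}"
                for u in graph.neighbors(v)
            )
            nxt[v] = _stable_hash(current[v] + "|" + ",".join(neigh))
        current = nxt
        rounds.append(dict(current))
    return rounds


def _bfs_distances(graph: nx.Graph, source, cutoff: int) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        if dist[v] >= cutoff:
            continue
        for u in graph.neighbors(v):
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


def nspdk_features(
    graph: nx.Graph, radius: int, distance: int, hash_bits: int
) -> sp.csr_matrix:
    """Neighborhood-pair features of one labelled graph.

    For every node pair at shortest-path distance d <= distance and every
    r <= radius, the (order-independent) pair of WL-canonical rooted
    neighborhood labels together with (r, d) is hashed into
    [0, 2**hash_bits); counts are L2-normalised.
    """
    width = 1 << hash_bits
    if graph.number_of_nodes() == 0:
        return sp.csr_matrix((1, width))
    labels = _wl_labels(graph, radius)
    nodes = sorted(graph.nodes)
    counts: Counter = Counter()
    for u in nodes:
        dists = _bfs_distances(graph, u, distance)
        for v, d in dists.items():
            if v < u:
                continue  # count each unordered pair once (u == v allowed)
            for r in range(radius + 1):
                lu, lv = labels[r][u], labels[r][v]
                if lv < lu:
                    lu, lv = lv, lu
                key = _stable_hash(f"{lu}|{lv}|{r}|{d}")
                counts[int(key, 16) % width] += 1
    if not counts:
        return sp.csr_matrix((1, width))
    idx = np.array(sorted(counts), dtype=np.int64)
    val = np.array([counts[i] for i in idx], dtype=float)
    val /= np.linalg.norm(val)
    return sp.csr_matrix((val, (np.zeros_like(idx), idx)), shape=(1, width))


# ---------------------------------------------------------------------------
# feature tables


@dataclass
class FeatureTable:
    """Feature matrix of one run: dense named block, optional sparse
    graph block, labels (NaN = unlabelled eval instance), NA ids for
    instances without predictions, and the config fingerprint."""

    ids: list
    dense: pd.DataFrame
    labels: np.ndarray
    sparse: sp.csr_matrix | None = None
    na_ids: list = field(default_factory=list)
    fingerprint: str = ""
    hash_bits: int | None = None
    provenance: list | None = None

    def __post_init__(self):
        if len(self.ids) != len(self.dense):
            raise ValueError("ids/dense length mismatch")
        if not np.isfinite(self.dense.to_numpy()).all():
            raise ValueError("non-finite value in dense feature block")

    @property
    def feature_names(self) -> list:
        return list(self.dense.columns)

    def matrix(self):
        """Combined dense + sparse design matrix."""
        if self.sparse is None:
            return self.dense.to_numpy()
        return sp.hstack(
            [sp.csr_matrix(self.dense.to_numpy()), self.sparse], format="csr"
        )

    def labelled_subset(self):
        keep = ~np.isnan(self.labels)
        return self._subset(np.nonzero(keep)[0])

    def _subset(self, idx):
        return FeatureTable(
            ids=[self.ids[i] for i in idx],
            dense=self.dense.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx],
            sparse=self.sparse[idx] if self.sparse is not None else None,
            na_ids=list(self.na_ids),
            fingerprint=self.fingerprint,
            hash_bits=self.hash_bits,
            provenance=[self.provenance[i] for i in idx]
            if self.provenance is not None
            else None,
        )

    def site_groups(self) -> list:
        """Site identifier per row (instance id without polarity suffix),
        so positive and negative instances of one site can share a CV
        fold."""
        return [i.rsplit("::", 1)[0] for i in self.ids]

    # -- serialization ------------------------------------------------------

    def write(self, dense_path, sparse_path=None) -> None:
        with open(dense_path, "w") as fh:
            fh.write(f"# config_fingerprint={self.fingerprint}\n")
            fh.write(f"# hash_bits={self.hash_bits if self.hash_bits is not None else 'none'}\n")
            out = self.dense.copy()
            out.insert(0, "instance_id", self.ids)
            out.insert(1, "label", self.labels)
            out.to_csv(fh, sep="\t", index=False, float_format="%.10g")
        if sparse_path is not None and self.sparse is not None:
            coo = self.sparse.tocoo()
            with open(sparse_path, "w") as fh:
                fh.write(f"# config_fingerprint={self.fingerprint}\n")
                fh.write(f"# hash_bits={self.hash_bits}\n")
                for r, c, v in zip(coo.row, coo.col, coo.data):
                    fh.write(f"{r}\t{c}\t{v:.10g}\n")

    @classmethod
    def read(cls, dense_path, sparse_path=None) -> "FeatureTable":
        with open(dense_path) as fh:
            fp = fh.readline().strip().split("=", 1)[1]
            bits = fh.readline().strip().split("=", 1)[1]
            df = pd.read_csv(fh, sep="\t")
        hash_bits = None if bits == "none" else int(bits)
        ids = df["instance_id"].tolist()
        labels = df["label"].to_numpy(dtype=float)
        dense = df.drop(columns=["instance_id", "label"])
        sparse = None
        if sparse_path is not None and hash_bits is not None:
            rows, cols, vals = [], [], []
            with open(sparse_path) as fh:
                for line in fh:
                    if line.startswith("#"):
                        continue
                    r, c, v = line.split("\t")
                    rows.append(int(r))
                    cols.append(int(c))
                    vals.append(float(v))
            sparse = sp.csr_matrix(
                (vals, (rows, cols)), shape=(len(ids), 1 << hash_bits)
            )
        return cls(
            ids=ids,
            dense=dense,
            labels=labels,
            sparse=sparse,
            fingerprint=fp,
            hash_bits=hash_bits,
        )


def featurize_instances(
    instances: list[PredictionInstance],
    config: Config | None = None,
    graph_features: bool = True,
    labelled: bool = True,
) -> FeatureTable:
    """Feature table over a list of instances, stable column order.

    Positive polarity maps to label 1, negative to 0; ``labelled=False``
    leaves labels NaN (eval mode). Instances without duplexes contribute
    no row and are listed in ``na_ids``.
    """
    config = config or Config()
    ids, rows, labels, na_ids, sparse_rows = [], [], [], [], []
    for inst in instances:
        feats = handcrafted_features(inst)
        if feats is None:
            na_ids.append(inst.instance_id)
            continue
        ids.append(inst.instance_id)
        rows.append(feats)
        if labelled:
            labels.append(1.0 if inst.polarity == "positive" else 0.0)
        else:
            labels.append(np.nan)
        if graph_features:
            g = build_interaction_graph(inst)
            sparse_rows.append(
                nspdk_features(
                    g, config.graph_radius, config.graph_distance, config.hash_bits
                )
            )
    columns = sorted(rows[0].keys()) if rows else []
    dense = pd.DataFrame(rows, columns=columns, dtype=float)
    sparse = sp.vstack(sparse_rows, format="csr") if sparse_rows else None
    if graph_features and not sparse_rows:
        sparse = sp.csr_matrix((0, 1 << config.hash_bits))
    return FeatureTable(
        ids=ids,
        dense=dense,
        labels=np.array(labels, dtype=float),
        sparse=sparse,
        na_ids=na_ids,
        fingerprint=config.fingerprint(),
        hash_bits=config.hash_bits if graph_features else None,
    )
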