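"""GCN and GATv2 graph-level classifiers.

Both architectures follow the same skeleton: 3 message-passing layers with
an edge-encoder MLP turning the scalar edge confidence into the quantity
the layer consumes (a positive aggregation coefficient for the
convolutional variant; an attention-input edge embedding for the attention
variant), batch normalisation, ReLU, dropout and a residual connection per
layer; readout is the concatenation of graph-wide mean and max pooling,
followed by a two-layer classification head producing 2 logits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ..errors import ConfigurationError, StructuralError
from ..graphs import PatientGraph
from . import autograd as ag
from .autograd import Tensor
from .config import GNNConfig
from .layers import MLP, BatchNorm, Linear, Module, dropout

EDGE_ENCODER_WIDTH = 16


@dataclass
class GraphBatch:
    """A disjoint union of patient graphs, PyG-style."""

    node_x: np.ndarray  # (total_nodes, d)
    edge_src: np.ndarray  # directed (both orientations of every edge)
    edge_dst: np.ndarray
    edge_w: np.ndarray  # (total_edges, 1)
    node_graph: np.ndarray  # (total_nodes,) graph membership
    n_graphs: int
    labels: np.ndarray | None = None
    # precomputed selection matrices: gathers are sparse row selections,
    # segment sums their transposes — much faster than np.add.at
    _mats: dict = field(default_factory=dict, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.node_x.shape[0]

    def _selection(self, idx: np.ndarray, n_cols: int, key: str):
        """(len(idx) x n_cols) CSR selecting rows ``idx``, plus transpose."""
        if key not in self._mats:
            m = sp.csr_matrix(
                (np.ones(len(idx), dtype=ag.default_dtype()),
                 (np.arange(len(idx)), idx)),
                shape=(len(idx), n_cols),
            )
            self._mats[key] = (m, sp.csr_matrix(m.T))
        return self._mats[key]

    @property
    def gather_src(self):
        return self._selection(self.edge_src, self.n_nodes, "src")

    @property
    def gather_dst(self):
        return self._selection(self.edge_dst, self.n_nodes, "dst")

    @property
    def pool(self):
        return self._selection(self.node_graph, self.n_graphs, "pool")


def collate(graphs: list[PatientGraph], with_labels: bool = False) -> GraphBatch:
    xs, srcs, dsts, ws, membership, labels = [], [], [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        xs.append(g.node_features)
        if g.n_edges:
            u = g.edge_index[:, 0] + offset
            v = g.edge_index[:, 1] + offset
            srcs.append(np.concatenate([u, v]))
            dsts.append(np.concatenate([v, u]))
            ws.append(np.concatenate([g.edge_weight, g.edge_weight]))
        membership.append(np.full(g.n_nodes, gi))
        if with_labels:
            if g.label is None:
                raise StructuralError(f"graph {g.patient_id} has no label")
            labels.append(g.label)
        offset += g.n_nodes
    return GraphBatch(
        node_x=np.vstack(xs),
        edge_src=np.concatenate(srcs) if srcs else np.empty(0, dtype=int),
        edge_dst=np.concatenate(dsts) if dsts else np.empty(0, dtype=int),
        edge_w=(np.concatenate(ws) if ws else np.empty(0)).reshape(-1, 1),
        node_graph=np.concatenate(membership),
        n_graphs=len(graphs),
        labels=np.asarray(labels, dtype=int) if with_labels else None,
    )


class GCNLayer(Module):
    """Degree-normalised weighted convolution with an edge-gating MLP."""

    def __init__(self, in_dim, out_dim, drop, rng):
        self.lin = Linear(in_dim, out_dim, rng)
        self.edge_mlp = MLP(1, EDGE_ENCODER_WIDTH, 1, rng)
        self.bn = BatchNorm(out_dim)
        self.res = Linear(in_dim, out_dim, rng, bias=False) if in_dim != out_dim else None
        self.drop = drop

    def __call__(self, h, batch: GraphBatch, training, rng):
        if batch.edge_src.size:
            g_src, g_src_t = batch.gather_src
            g_dst, g_dst_t = batch.gather_dst
            s = ag.softplus(self.edge_mlp(ag.constant(batch.edge_w)))
            msg = ag.mul(ag.spmm(g_src, h, g_src_t), s)
            agg = ag.spmm(g_dst_t, msg, g_dst)
            deg = ag.spmm(g_dst_t, s, g_dst)
            combined = ag.div(ag.add(agg, h), ag.add(deg, ag.constant(1.0)))
        else:
            combined = h
        y = self.lin(combined)
        y = self.bn(y, training)
        y = ag.relu(y)
        y = dropout(y, self.drop, rng, training)
        skip = h if self.res is None else self.res(h)
        return ag.add(y, skip)


class GATv2Layer(Module):
    """Multi-head dynamic attention with edge embeddings in the score.

    All heads are evaluated in one fused pass: source/target transforms
    produce ``heads * head_dim`` columns, the per-head attention vectors
    live in a block-diagonal matrix, and the per-head softmax runs on one
    (edges x heads) score array.
    """

    def __init__(self, in_dim, head_dim, heads, drop, rng, average_heads=False):
        self.heads = heads
        self.head_dim = head_dim
        self.average = average_heads
        wide = heads * head_dim
        self.w_src = Linear(in_dim, wide, rng)
        self.w_dst = Linear(in_dim, wide, rng, bias=False)
        scale = np.sqrt(2.0 / (head_dim + 1))
        from .autograd import Tensor as _T

        self.att = _T(rng.normal(0.0, scale, (wide, heads)), True)
        # mask confines each head's attention vector to its own block
        mask = np.zeros((wide, heads))
        for k in range(heads):
            mask[k * head_dim : (k + 1) * head_dim, k] = 1.0
        self.att_mask = mask
        self.edge_mlp = MLP(1, EDGE_ENCODER_WIDTH, wide, rng)
        out_dim = head_dim if average_heads else wide
        self.bn = BatchNorm(out_dim)
        self.res = Linear(in_dim, out_dim, rng, bias=False) if in_dim != out_dim else None
        self.drop = drop

    def __call__(self, h, batch: GraphBatch, training, rng):
        n = batch.n_nodes
        if batch.edge_src.size:
            g_src, g_src_t = batch.gather_src
            g_dst, g_dst_t = batch.gather_dst
            edge_emb = self.edge_mlp(ag.constant(batch.edge_w))
            z_src = ag.spmm(g_src, self.w_src(h), g_src_t)
            z_dst = ag.spmm(g_dst, self.w_dst(h), g_dst_t)
            e = ag.leaky_relu(ag.add(ag.add(z_src, z_dst), edge_emb), 0.2)
            score = ag.matmul(e, ag.mul(self.att, ag.constant(self.att_mask)))
            alpha = ag.segment_softmax(score, batch.edge_dst, n,
                                       scatter=g_dst_t, gather_mat=g_dst)
            msg = ag.mul(z_src, ag.repeat_cols(alpha, self.head_dim))
            y = ag.spmm(g_dst_t, msg, g_dst)
        else:
            # no edges: fall back to per-node transform so shapes still work
            y = self.w_src(h)
        if self.average:
            y = ag.block_mean_cols(y, self.heads)
        y = self.bn(y, training)
        y = ag.relu(y)
        y = dropout(y, self.drop, rng, training)
        skip = h if self.res is None else self.res(h)
        return ag.add(y, skip)


class GNNModel(Module):
    """3-layer message-passing network with mean+max readout and a 2-layer head."""

    def __init__(self, config: GNNConfig, node_dim: int):
        config.validate()
        if node_dim not in (1, 5):
            raise ConfigurationError("node_dim must be 1 or 5")
        self.config = config
        self.node_dim = node_dim
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0x6E6E])
        )
        h = config.hidden_dim
        dims = [node_dim] + [h] * config.n_layers
        self.layers: list[Module] = []
        for li in range(config.n_layers):
            last = li == config.n_layers - 1
            if config.architecture == "gcn":
                self.layers.append(GCNLayer(dims[li], h, config.dropout, rng))
            else:
                if last:
                    layer = GATv2Layer(dims[li], h, config.heads, config.dropout, rng,
                                       average_heads=True)
                else:
                    if h % config.heads:
                        raise ConfigurationError("hidden_dim must be divisible by heads")
                    layer = GATv2Layer(dims[li], h // config.heads, config.heads,
                                       config.dropout, rng)
                self.layers.append(layer)
        self.head1 = Linear(2 * h, h, rng)
        self.head2 = Linear(h, 2, rng)
        # input normalisation (set from training-fold graphs in `train`);
        # the 5-dim node features mix scales from ~0.01 (betweenness) to
        # ~N (strength), which otherwise skews optimisation
        self.input_mean = np.zeros(node_dim)
        self.input_sd = np.ones(node_dim)

    def set_input_stats(self, graphs: list[PatientGraph]) -> None:
        x = np.vstack([g.node_features for g in graphs])
        self.input_mean = x.mean(axis=0)
        sd = x.std(axis=0)
        self.input_sd = np.where(sd > 1e-8, sd, 1.0)

    def forward(self, batch: GraphBatch, training: bool,
                rng: np.random.Generator | None = None) -> Tensor:
        if batch.node_x.shape[1] != self.node_dim:
            raise StructuralError(
                f"model expects node_dim={self.node_dim}, "
                f"got {batch.node_x.shape[1]}"
            )
        if rng is None:
            rng = np.random.default_rng(0)
        h = ag.constant((batch.node_x - self.input_mean) / self.input_sd)
        for layer in self.layers:
            h = layer(h, batch, training, rng)
        counts = np.bincount(batch.node_graph, minlength=batch.n_graphs)
        pool, pool_t = batch.pool
        mean_pool = ag.div(
            ag.spmm(pool_t, h, pool),
            ag.constant(counts.reshape(-1, 1).astype(float)),
        )
        max_pool = ag.segment_max(h, batch.node_graph, batch.n_graphs)
        z = ag.concat([mean_pool, max_pool], axis=1)
        z = ag.relu(self.head1(z))
        z = dropout(z, self.config.dropout, rng, training)
        return self.head2(z)


def build_model(config: GNNConfig, node_dim: int) -> GNNModel:
    """Construct a graph classifier for 1- or 5-dimensional node features."""
    return GNNModel(config, node_dim)
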