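"""Numpy core of the distance-based atomistic network.

The network is SchNet-class: a learnable per-element embedding, a stack of
interaction blocks performing continuous-filter convolutions over a radial
neighbourhood graph, and an atom-wise readout whose per-atom scalars are
summed into a single value per conformation.  Only interatomic distances enter
the model (no bonds, no angles), so the output is invariant to translations,
rotations, reflections, and atom permutations by construction.

Forward and backward passes are written explicitly so the package has no
deep-learning framework dependency; gradients are validated against finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.special import expit

from .errors import DimensionError, VocabularyError

__all__ = ["AtomicGraph", "build_graph", "rbf_expand", "SchNetCore"]

_LOG2 = float(np.log(2.0))


@dataclass
class AtomicGraph:
    """Radial neighbourhood graph of a heavy-atom point cloud."""

    atomic_numbers: np.ndarray  # (N,)
    coords: np.ndarray  # (N, 3) Å
    src: np.ndarray  # (M,) edge sources
    dst: np.ndarray  # (M,) edge destinations
    distances: np.ndarray  # (M,) Å

    @property
    def n_atoms(self) -> int:
        return self.atomic_numbers.shape[0]


def build_graph(atomic_numbers, coords, cutoff: float) -> AtomicGraph:
    """All ordered pairs (i, j), i != j, with interatomic distance <= cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    z = np.asarray(atomic_numbers, dtype=np.int64)
    x = np.asarray(coords, dtype=float)
    if x.shape != (z.shape[0], 3):
        raise DimensionError(f"coords shape {x.shape} does not match {z.shape[0]} atoms")
    delta = x[:, None, :] - x[None, :, :]
    dist = np.sqrt((delta**2).sum(-1))
    mask = (dist <= cutoff) & ~np.eye(z.shape[0], dtype=bool)
    src, dst = np.nonzero(mask)
    return AtomicGraph(atomic_numbers=z, coords=x, src=src, dst=dst, distances=dist[src, dst])


def rbf_expand(d, n_rbf: int, cutoff: float) -> np.ndarray:
    """Gaussian radial basis values with centres evenly spaced on [0, cutoff].

    The Gaussian width is tied to the centre spacing, so each component equals
    1 exactly when the distance sits on its centre.
    """
    d = np.atleast_1d(np.asarray(d, dtype=float))
    centers = np.linspace(0.0, cutoff, n_rbf)
    spacing = centers[1] - centers[0] if n_rbf > 1 else cutoff
    gamma = 1.0 / (2.0 * spacing**2)
    return np.exp(-gamma * (d[:, None] - centers[None, :]) ** 2)


def _ssp(x: np.ndarray) -> np.ndarray:
    """Shifted softplus: log(0.5 e^x + 0.5); smooth, ssp(0) = 0."""
    return np.logaddexp(0.0, x) - _LOG2


def _cosine_cutoff(d: np.ndarray, cutoff: float) -> np.ndarray:
    return np.where(d <= cutoff, 0.5 * (np.cos(np.pi * d / cutoff) + 1.0), 0.0)


class SchNetCore:
    """Parameters plus explicit forward/backward of the SchNet-class network.

    ``vocab`` maps atomic numbers to embedding rows; atoms outside it raise
    :class:`VocabularyError`.
    """

    def __init__(
        self,
        vocab: dict[int, int],
        embed_dim: int = 128,
        n_interactions: int = 6,
        n_rbf: int = 50,
        cutoff: float = 10.0,
        readout_hidden: int = 64,
        rng: np.random.Generator | None = None,
    ):
        if min(embed_dim, n_interactions, n_rbf, readout_hidden) < 1 or cutoff <= 0:
            raise ValueError("all model dimensions must be positive")
        self.vocab = dict(vocab)
        self.embed_dim = embed_dim
        self.n_interactions = n_interactions
        self.n_rbf = n_rbf
        self.cutoff = cutoff
        self.readout_hidden = readout_hidden
        rng = rng or np.random.default_rng(0)
        self.params = self._init_params(rng)

    def _xavier(self, rng, fan_in, fan_out):
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-bound, bound, size=(fan_in, fan_out))

    def _init_params(self, rng) -> dict[str, np.ndarray]:
        f, h, r = self.embed_dim, self.readout_hidden, self.n_rbf
        p: dict[str, np.ndarray] = {"embed": rng.normal(0.0, 1.0, size=(len(self.vocab), f))}
        for t in range(self.n_interactions):
            p[f"b{t}_Wf1"] = self._xavier(rng, r, f)
            p[f"b{t}_bf1"] = np.zeros(f)
            p[f"b{t}_Wf2"] = self._xavier(rng, f, f)
            p[f"b{t}_bf2"] = np.zeros(f)
            p[f"b{t}_Win"] = self._xavier(rng, f, f)
            p[f"b{t}_Wd1"] = self._xavier(rng, f, f)
            p[f"b{t}_bd1"] = np.zeros(f)
            p[f"b{t}_Wd2"] = self._xavier(rng, f, f)
            p[f"b{t}_bd2"] = np.zeros(f)
        p["Wr1"] = self._xavier(rng, f, h)
        p["br1"] = np.zeros(h)
        p["Wr2"] = self._xavier(rng, h, 1)
        p["br2"] = np.zeros(1)
        return p

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    def _z_index(self, atomic_numbers: np.ndarray) -> np.ndarray:
        try:
            return np.array([self.vocab[int(z)] for z in atomic_numbers], dtype=np.int64)
        except KeyError as exc:
            raise VocabularyError(
                f"atomic number {exc.args[0]} not in embedding table {sorted(self.vocab)}"
            ) from exc

    @staticmethod
    def _merge(graphs: list[AtomicGraph]):
        """Concatenate graphs into one disconnected union with segment ids."""
        offsets = np.cumsum([0] + [g.n_atoms for g in graphs])
        z = np.concatenate([g.atomic_numbers for g in graphs])
        src = np.concatenate([g.src + off for g, off in zip(graphs, offsets)])
        dst = np.concatenate([g.dst + off for g, off in zip(graphs, offsets)])
        d = np.concatenate([g.distances for g in graphs])
        seg = np.repeat(np.arange(len(graphs)), [g.n_atoms for g in graphs])
        return z, src, dst, d, seg

    def forward_batch(self, graphs: list[AtomicGraph], want_cache: bool = False):
        """Predictions for a batch of graphs (message passing cannot cross
        disconnected components, so batching is exact)."""
        p = self.params
        z_all, src, dst, d, seg = self._merge(graphs)
        n = z_all.shape[0]
        m = src.shape[0]
        z_idx = self._z_index(z_all)
        e = rbf_expand(d, self.n_rbf, self.cutoff)
        fc = _cosine_cutoff(d, self.cutoff)
        ones = np.ones(m)
        # sparse scatter operators: rows = atoms, cols = edges
        sc_dst = csr_matrix((ones, (dst, np.arange(m))), shape=(n, m))
        sc_src = csr_matrix((ones, (src, np.arange(m))), shape=(n, m))
        x = p["embed"][z_idx]
        blocks = []
        for t in range(self.n_interactions):
            f1 = e @ p[f"b{t}_Wf1"] + p[f"b{t}_bf1"]
            g1 = _ssp(f1)
            w = (g1 @ p[f"b{t}_Wf2"] + p[f"b{t}_bf2"]) * fc[:, None]
            a = x @ p[f"b{t}_Win"]
            msg = a[src] * w
            s = sc_dst @ msg
            h1 = s @ p[f"b{t}_Wd1"] + p[f"b{t}_bd1"]
            g2 = _ssp(h1)
            v = g2 @ p[f"b{t}_Wd2"] + p[f"b{t}_bd2"]
            if want_cache:
                blocks.append({"x_in": x, "f1": f1, "g1": g1, "w": w, "a": a, "s": s, "h1": h1, "g2": g2})
            x = x + v
        r1 = x @ p["Wr1"] + p["br1"]
        gr = _ssp(r1)
        y_atom = gr @ p["Wr2"] + p["br2"]
        y = np.bincount(seg, weights=y_atom[:, 0], minlength=len(graphs))
        if not want_cache:
            return y
        cache = {
            "z_idx": z_idx, "e": e, "fc": fc, "x_out": x, "r1": r1, "gr": gr,
            "blocks": blocks, "src": src, "dst": dst, "seg": seg,
            "sc_dst": sc_dst, "sc_src": sc_src, "n_atoms": n,
        }
        return y, cache

    def forward(self, graph: AtomicGraph, want_cache: bool = False):
        """Scalar prediction for one graph; optionally the backprop cache."""
        out = self.forward_batch([graph], want_cache=want_cache)
        if want_cache:
            return float(out[0][0]), out[1]
        return float(out[0])

    def backward(self, cache: dict, dy, grads: dict[str, np.ndarray]) -> None:
        """Accumulate parameter gradients into ``grads``.

        ``dy`` is the loss gradient per graph in the batch (scalar allowed for
        a single graph).
        """
        p = self.params
        src, dst, seg = cache["src"], cache["dst"], cache["seg"]
        d_y_atom = np.atleast_1d(np.asarray(dy, dtype=float))[seg][:, None]
        grads["Wr2"] += cache["gr"].T @ d_y_atom
        grads["br2"] += d_y_atom.sum(axis=0)
        d_gr = d_y_atom @ p["Wr2"].T
        d_r1 = d_gr * expit(cache["r1"])
        grads["Wr1"] += cache["x_out"].T @ d_r1
        grads["br1"] += d_r1.sum(axis=0)
        d_x = d_r1 @ p["Wr1"].T
        for t in reversed(range(self.n_interactions)):
            blk = cache["blocks"][t]
            d_v = d_x  # residual: d_x also flows to x_in directly
            grads[f"b{t}_Wd2"] += blk["g2"].T @ d_v
            grads[f"b{t}_bd2"] += d_v.sum(axis=0)
            d_g2 = d_v @ p[f"b{t}_Wd2"].T
            d_h1 = d_g2 * expit(blk["h1"])
            grads[f"b{t}_Wd1"] += blk["s"].T @ d_h1
            grads[f"b{t}_bd1"] += d_h1.sum(axis=0)
            d_s = d_h1 @ p[f"b{t}_Wd1"].T
            d_msg = d_s[dst]
            d_a = cache["sc_src"] @ (d_msg * blk["w"])
            d_w = d_msg * blk["a"][src]
            grads[f"b{t}_Win"] += blk["x_in"].T @ d_a
            d_x = d_x + d_a @ p[f"b{t}_Win"].T
            d_wf = d_w * cache["fc"][:, None]
            grads[f"b{t}_Wf2"] += blk["g1"].T @ d_wf
            grads[f"b{t}_bf2"] += d_wf.sum(axis=0)
            d_g1 = d_wf @ p[f"b{t}_Wf2"].T
            d_f1 = d_g1 * expit(blk["f1"])
            grads[f"b{t}_Wf1"] += cache["e"].T @ d_f1
            grads[f"b{t}_bf1"] += d_f1.sum(axis=0)
        np.add.at(grads["embed"], cache["z_idx"], d_x)
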