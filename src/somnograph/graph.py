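"""Electrode graphs: physical adjacency, normalization, dynamic graphs.

The spatial structure of the network rests on three matrices over the N
electrodes: a fixed 0/1 physical adjacency Gp derived from the montage,
a trainable real-valued mask Gm added to it, and a per-sample dynamic
adjacency Gd computed from the node features themselves.  Graph
convolutions use the symmetrically normalized form
D̃^{-1/2}(A+I)D̃^{-1/2}.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .autodiff import Tensor, pairwise_edge_scores

__all__ = [
    "MONTAGE_PRESETS",
    "load_montage",
    "physical_adjacency",
    "normalize_adjacency",
    "dynamic_graph",
    "SleepGraph",
]

MONTAGE_PRESETS = ("isruc6", "sleepedf2", "generic_10_20")

#: Reference suffixes commonly appended to 10-20 site labels.
_REF_SUFFIXES = ("-A1", "-A2", "-M1", "-M2", "-LER", "-REF")


def _strip_reference(label: str) -> str:
    up = label.strip()
    for suf in _REF_SUFFIXES:
        if up.upper().endswith(suf):
            return up[: -len(suf)]
    return up


def load_montage(name_or_path: str | Path) -> tuple[list[str], list[tuple[str, str]]]:
    """Load a montage preset by name, or a custom YAML file by path.

    The YAML holds ``labels`` (electrode names) and ``edges`` (undirected
    label pairs).
    """
    if isinstance(name_or_path, str) and name_or_path in MONTAGE_PRESETS:
        ref = resources.files("somnograph").joinpath(
            f"montages/{name_or_path}.yaml")
        doc = yaml.safe_load(ref.read_text())
    else:
        doc = yaml.safe_load(Path(name_or_path).read_text())
    labels = [str(x) for x in doc["labels"]]
    edges = [(str(a), str(b)) for a, b in doc["edges"]]
    return labels, edges


def physical_adjacency(montage: list[str],
                       edges: list[tuple[str, str]] | None = None,
                       preset: str | Path | None = None) -> np.ndarray:
    """Symmetric 0/1 adjacency over the requested electrodes.

    Edge sources, in order of precedence: an explicit ``edges`` list; a
    named preset / YAML path; edges among canonical 10-20 sites from the
    generic neighbor table (reference suffixes such as ``-A2`` are
    stripped before lookup).  A two-electrode montage with no other
    information defaults to the single possible connected graph.
    """
    n = len(montage)
    A = np.zeros((n, n))
    if n == 1:
        return A
    index = {lab: i for i, lab in enumerate(montage)}

    if edges is None and preset is not None:
        _, edges = load_montage(preset)
    if edges is None:
        stripped = {_strip_reference(lab): lab for lab in montage}
        g_labels, g_edges = load_montage("generic_10_20")
        known = set(g_labels)
        if set(stripped) <= known:
            edges = [(stripped[a], stripped[b]) for a, b in g_edges
                     if a in stripped and b in stripped]
        elif n == 2:
            edges = [(montage[0], montage[1])]
        else:
            unknown = sorted(set(stripped) - known)
            raise KeyError(
                f"montage labels {unknown} are not canonical 10-20 sites; "
                "supply an explicit edge list or preset")

    for a, b in edges:
        a, b = _strip_reference(a), _strip_reference(b)
        stripped_index = {_strip_reference(lab): i for lab, i in index.items()}
        if a not in stripped_index or b not in stripped_index:
            raise KeyError(f"edge ({a}, {b}) references electrodes outside "
                           f"the montage {montage}")
        i, j = stripped_index[a], stripped_index[b]
        if i != j:
            A[i, j] = A[j, i] = 1.0
    return A


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric GCN normalization D̃^{-1/2}·(A+I)·D̃^{-1/2}.

    Self-loops are added before computing the diagonal degree matrix D̃,
    so an edgeless graph normalizes to the identity.
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if (A < 0).any():
        raise ValueError("adjacency entries must be non-negative")
    A_tilde = A + np.eye(A.shape[0])
    d = A_tilde.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    return A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


@dataclass
class SleepGraph:
    """The static electrode graph: physical adjacency plus trainable mask.

    ``gp_norm`` caches the normalized physical adjacency; ``gm`` starts
    at zero so the static branch begins exactly at the physical topology.
    """

    montage: list[str]
    gp: np.ndarray
    gp_norm: np.ndarray
    gm_init: np.ndarray

    @classmethod
    def from_montage(cls, montage: list[str],
                     edges: list[tuple[str, str]] | None = None,
                     preset: str | Path | None = None) -> "SleepGraph":
        gp = physical_adjacency(montage, edges=edges, preset=preset)
        return cls(montage=list(montage), gp=gp,
                   gp_norm=normalize_adjacency(gp),
                   gm_init=np.zeros_like(gp))


def dynamic_graph(X, w):
    """Per-frame dynamic adjacency from node features.

    Edge score s(i,j) = max(0, wᵀ|x_i − x_j|), normalized per row with a
    softmax, so rows sum to 1 and all entries are non-negative.  When all
    node features coincide every row is uniform (1/N).  Accepts numpy
    arrays or autodiff tensors; with tensors the result is differentiable
    in both ``X`` and ``w``.

    ``X`` is (N, F) for a single frame, or any (..., N, F) stack of
    frames; ``w`` has length F.
    """
    xt = X if isinstance(X, Tensor) else Tensor(np.asarray(X, dtype=float))
    wt = w if isinstance(w, Tensor) else Tensor(np.asarray(w, dtype=float))
    if xt.shape[-1] != wt.shape[-1]:
        raise ValueError(
            f"w has {wt.shape[-1]} weights but features have {xt.shape[-1]}")
    gd = pairwise_edge_scores(xt, wt).softmax(axis=-1)
    if isinstance(X, Tensor) or isinstance(w, Tensor):
        return gd
    return gd.data
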