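"""Descriptor-swap baselines: alternative ligand featurisations.

Two comparison routes are provided for any ligand descriptor table:
(a) the same two-sigmoid energy head trained with the graph network removed
    (the descriptor vector stands in for the GNN output), via
    `training.build_feature_dataset` + `training.train_two_stage`;
(b) a restricted linear regression — non-negative coefficients, zero
    intercept — of the rate constant on [hammett ⊕ descriptor] features.

Descriptor kinds: one-hot ligand identity; hashed circular-substructure
count fingerprints (a simplified stand-in for multi-fingerprint features,
computed on the ligand trees at radii 1-3); or user-supplied numeric
columns such as buried volumes and cone angles, which are input data here,
never computed.
"""

from __future__ import annotations

import zlib
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .errors import DegenerateDesignError
from .ligand_tree import LigandTree, ROOT

DESCRIPTOR_KINDS = ("one_hot", "fingerprint", "numeric_file")


def restricted_linear_fit(features, k_obs) -> np.ndarray:
    """Least squares with coefficients >= 0 and intercept fixed at 0.

    Solves min ||X c - k||^2 subject to c >= 0 (classical NNLS).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(k_obs, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("feature matrix and response length mismatch")
    if not np.any(X):
        raise DegenerateDesignError("all-zero feature matrix")
    coef, _ = scipy.optimize.nnls(X, y)
    return coef


def _stable_hash(obj) -> int:
    # process-independent (unlike builtin hash, which salts strings)
    return zlib.crc32(repr(obj).encode())


def _wl_hashes(tree: LigandTree, radius: int) -> list[int]:
    """Weisfeiler-Lehman-style neighborhood hashes after `radius` rounds."""
    adj: dict[object, list[tuple[object, float]]] = {ROOT: []}
    labels: dict[object, int] = {ROOT: _stable_hash("P")}
    for nid in tree.nodes:
        adj[nid] = []
        labels[nid] = _stable_hash("C")
    for u, v, order in tree.edges:
        adj[u].append((v, order))
        adj[v].append((u, order))
    for _ in range(radius):
        labels = {
            n: _stable_hash(
                (labels[n], tuple(sorted((order, labels[nb]) for nb, order in adj[n])))
            )
            for n in labels
        }
    return [labels[n] for n in labels]


def _fingerprint(tree: LigandTree, n_bits: int, radii: Sequence[int]) -> np.ndarray:
    counts = np.zeros(n_bits * len(radii))
    for block, radius in enumerate(radii):
        for h in _wl_hashes(tree, radius):
            counts[block * n_bits + h % n_bits] += 1.0
    return counts


def build_descriptor_table(
    ligands: Sequence[LigandTree] | Sequence[str],
    kind: str,
    numeric_path=None,
    n_bits: int = 64,
    radii: Sequence[int] = (1, 2, 3),
) -> pd.DataFrame:
    """Per-ligand feature table (rows indexed by ligand id).

    one_hot needs only ligand ids; fingerprint needs trees; numeric_file
    reads ``numeric_path`` (CSV: ligand, feature1, ...) verbatim and checks
    every requested ligand has a row.
    """
    if kind not in DESCRIPTOR_KINDS:
        raise ValueError(f"unknown descriptor kind {kind!r}; choose {DESCRIPTOR_KINDS}")
    names = [l.name if isinstance(l, LigandTree) else str(l) for l in ligands]
    if kind == "one_hot":
        table = pd.DataFrame(np.eye(len(names)), index=names)
    elif kind == "fingerprint":
        if not all(isinstance(l, LigandTree) for l in ligands):
            raise TypeError("fingerprint descriptors require LigandTree inputs")
        table = pd.DataFrame(
            np.stack([_fingerprint(l, n_bits, radii) for l in ligands]), index=names
        )
    else:
        if numeric_path is None:
            raise ValueError("numeric_file descriptors need numeric_path")
        raw = pd.read_csv(numeric_path)
        raw = raw.set_index(raw.columns[0])
        missing = sorted(set(names) - set(raw.index))
        if missing:
            raise KeyError(f"numeric descriptor file lacks rows for: {missing}")
        table = raw.loc[names].astype(float)
    table.index.name = "ligand_id"
    table.columns = [str(c) for c in table.columns]
    return table
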