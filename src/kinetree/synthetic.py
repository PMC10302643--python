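"""Synthetic ligand sets and reaction tables with known energy structure.

The generator emulates the design of the Plenio Sonogashira kinetics
screen: a panel of trialkyl/arylalkyl phosphines spanning a steric gradient,
crossed with mono-substituted aryl bromides spanning the usual Hammett
range, giving a full-factorial rate-constant table (17 x 20 = 340 by
default).  Ground truth is an additive two-component barrier,

    dG_L*  = max(0, a0 - a1 * s)                (ligand-only, bulk lowers it)
    dG_LS* = max(0, b0 + b1 * s - b2 * sigma)   (cooperative term)
    dG     = dG_L* + dG_LS* + eps,   eps ~ N(0, noise_sd)

with s the steric proxy (node count within 3 bonds of P) and sigma the
effective Hammett constant of the substrate.  Rates follow by the Eyring
equation at the generator temperature.  The defaults make dG_LS* the larger
component and give bulkier ligands faster rates overall, matching the
qualitative physics of ligand-accelerated oxidative addition; the true
components are recorded per row so that recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import DEFAULT_TEMPERATURE_K, eyring_rate_from_energy
from .ligand_tree import LigandTree, build_tree
from .substrate import HammettTable, encode_substrate, load_hammett_table


@dataclass(frozen=True)
class GenerativeTruth:
    """Parameters of the additive ground-truth barrier (kcal/mol)."""

    a0: float = 12.0
    a1: float = 0.3
    b0: float = 14.0
    b1: float = 0.1
    b2: float = 2.0
    noise_sd: float = 0.05
    T: float = DEFAULT_TEMPERATURE_K

    def dG_L(self, s):
        return np.maximum(0.0, self.a0 - self.a1 * np.asarray(s, dtype=float))

    def dG_LS(self, s, sigma_eff):
        return np.maximum(
            0.0,
            self.b0
            + self.b1 * np.asarray(s, dtype=float)
            - self.b2 * np.asarray(sigma_eff, dtype=float),
        )


# substituent pools ordered by increasing bulk near phosphorus; the
# "minimal" law walks acyclic alkyls from methyl to tert-butyl, "varied"
# adds rings and adamantyl and jitters branches individually
_POOLS = {
    "minimal": ["methyl", "ethyl", "n-propyl", "n-butyl", "tBu"],
    "varied": [
        "methyl", "ethyl", "n-propyl", "isopropyl", "n-butyl",
        "benzyl", "tBu", "cyclopentyl", "cyclohexyl", "adamantyl",
    ],
}

BRANCHING_LAWS = tuple(_POOLS)


def generate_ligand_set(
    n_ligands: int, branching_law: str = "varied", seed: int = 0
) -> list[LigandTree]:
    """Phosphine trees spanning a bulk gradient, reproducible per seed.

    ``minimal`` assigns all three branches of ligand i the pool substituent
    at fractional position i/(n-1) (so n=2 gives a PMe3-like and a
    PtBu3-like ligand); ``varied`` jitters each branch by one pool step to
    break threefold symmetry.  Steric proxies span at least min(n, 3)
    distinct values.
    """
    if n_ligands < 2:
        raise ValueError("need at least 2 ligands")
    if branching_law not in BRANCHING_LAWS:
        raise ValueError(
            f"unknown branching law {branching_law!r}; choose from {BRANCHING_LAWS}"
        )
    rng = np.random.default_rng(seed)
    pool = _POOLS[branching_law]
    need_distinct = min(n_ligands, 3)
    for _attempt in range(64):
        trees = []
        for i in range(n_ligands):
            level = i / (n_ligands - 1)
            base = round(level * (len(pool) - 1))
            subs = []
            for _branch in range(3):
                idx = base
                if branching_law == "varied":
                    idx += int(rng.integers(-1, 2))
                subs.append(pool[int(np.clip(idx, 0, len(pool) - 1))])
            trees.append(build_tree(subs, name=f"SL{i + 1:02d}"))
        if len({t.steric_proxy() for t in trees}) >= need_distinct:
            return trees
    raise RuntimeError("could not realise enough distinct steric proxies")


def default_substrate_set() -> list[tuple[str, str]]:
    """20 (substituent, position) pairs spanning sigma in [-0.8, 0.8]."""
    para = ["NH2", "OMe", "tBu", "Me", "H", "F", "Cl", "CO2Me", "COMe",
            "CF3", "CN", "NO2"]
    meta = ["NH2", "Me", "OMe", "Cl", "Br", "CF3", "CN", "NO2"]
    return [(s, "para") for s in para] + [(s, "meta") for s in meta]


@dataclass
class SyntheticDataset:
    reactions: pd.DataFrame
    truth: pd.DataFrame
    ligands: list[LigandTree] = field(repr=False)
    generative: GenerativeTruth = field(default_factory=GenerativeTruth)


def generate_reaction_dataset(
    ligands: list[LigandTree],
    substrates: list[tuple[str, str]] | None = None,
    truth: GenerativeTruth | None = None,
    seed: int = 0,
    hammett_table: HammettTable | None = None,
) -> SyntheticDataset:
    """Full-factorial ligand x substrate rate table plus its truth table."""
    truth = truth or GenerativeTruth()
    substrates = substrates if substrates is not None else default_substrate_set()
    table = hammett_table or load_hammett_table()
    rng = np.random.default_rng(seed)

    rows = []
    for lig in ligands:
        s = lig.steric_proxy()
        for sub, pos in substrates:
            hv = encode_substrate(sub, pos, table)
            rows.append((lig.name, sub, pos, s, hv.sigma_eff))
    df = pd.DataFrame(
        rows, columns=["ligand_id", "substituent", "position", "s", "sigma_eff"]
    )
    dG_L = truth.dG_L(df["s"].to_numpy())
    dG_LS = truth.dG_LS(df["s"].to_numpy(), df["sigma_eff"].to_numpy())
    noise = rng.normal(0.0, truth.noise_sd, size=len(df)) if truth.noise_sd else (
        np.zeros(len(df))
    )
    dG = dG_L + dG_LS + noise
    k = eyring_rate_from_energy(dG, truth.T)

    reactions = pd.DataFrame(
        {
            "ligand_id": df["ligand_id"],
            "substituent": df["substituent"],
            "position": df["position"],
            "k_obs": k,
            "temperature_K": truth.T,
        }
    )
    truth_df = df.assign(
        dG_L_true=dG_L, dG_LS_true=dG_LS, noise=noise, dG_true=dG
    )
    return SyntheticDataset(
        reactions=reactions, truth=truth_df, ligands=ligands, generative=truth
    )
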