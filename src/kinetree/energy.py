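"""Decomposed activation-energy head and Eyring rate conversions.

The total activation free energy of one coupling reaction is modelled as
the sum of two non-negative parts:

    dG  =  dG_LS + dG_L
    dG_LS = w_final[0] * sigmoid( w_h1 . [sigma_meta, sigma_para, g] )
    dG_L  = w_final[1] * sigmoid( w_h2 . g )          (w_h2, w_final >= 0)

where g is the ligand's GNN output vector.  dG_L depends on the ligand
alone (the steric barrier contribution); dG_LS couples ligand and substrate
(the cooperative oxidative-addition term).  All heads are single linear
units with no bias; w_h1 and w_h2 carry an L2 penalty; w_h2 and w_final are
constrained non-negative so that each component is a bounded, non-negative
energy (0 <= dG_L <= w_final[1], 0 <= dG_LS <= w_final[0]).

Rates and energies interconvert through the Eyring equation

    k = (k_B T / h) exp(-dG / (R T)),

with energies in kcal/mol and temperature in kelvin.  Activation energy and
activation free energy are used interchangeably here (the transmission
coefficient is taken as 1 and entropic factors are absorbed into dG).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConstraintError
from .substrate import HammettVector

# CODATA 2018 exact values
BOLTZMANN_J_PER_K = 1.380649e-23
PLANCK_J_S = 6.62607015e-34
GAS_CONSTANT_KCAL = 8.31446261815324 / 4184.0  # kcal mol^-1 K^-1

DEFAULT_TEMPERATURE_K = 298.15


def eyring_prefactor(temperature_K):
    """k_B T / h, the attempt frequency, in s^-1."""
    t = np.asarray(temperature_K, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive")
    return BOLTZMANN_J_PER_K * t / PLANCK_J_S


def eyring_rate_from_energy(energy_kcal, temperature_K):
    """k = (k_B T / h) exp(-dG / RT); strictly decreasing in dG."""
    e = np.asarray(energy_kcal, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("activation energy must be finite")
    return eyring_prefactor(temperature_K) * np.exp(
        -e / (GAS_CONSTANT_KCAL * np.asarray(temperature_K, dtype=float))
    )


def eyring_energy_from_rate(rate, temperature_K):
    """dG = RT ln(k_B T / (h k)); exact inverse of eyring_rate_from_energy."""
    k = np.asarray(rate, dtype=float)
    if np.any(k <= 0) or not np.all(np.isfinite(k)):
        raise ValueError("rate constant must be positive and finite")
    t = np.asarray(temperature_K, dtype=float)
    return GAS_CONSTANT_KCAL * t * np.log(eyring_prefactor(t) / k)


@dataclass
class EnergyHeadParams:
    """Weights of the two sigmoid heads and the final combination layer."""

    w_h1: np.ndarray  # (2 + S,), acts on [hammett ⊕ gnn_out]
    w_h2: np.ndarray  # (S,), non-negative, acts on gnn_out
    w_final: np.ndarray  # (2,), non-negative: scales (dG_LS, dG_L)
    l2_strength: float = 0.0

    def __post_init__(self):
        self.w_h1 = np.asarray(self.w_h1, dtype=float).ravel()
        self.w_h2 = np.asarray(self.w_h2, dtype=float).ravel()
        self.w_final = np.asarray(self.w_final, dtype=float).ravel()
        if self.w_final.shape != (2,):
            raise ValueError("w_final must have exactly 2 entries")
        if self.w_h1.shape != (2 + self.n_slots,):
            raise ValueError("w_h1 must have length 2 + len(w_h2)")

    @property
    def n_slots(self) -> int:
        return self.w_h2.size

    def validate(self) -> None:
        """Refuse to run with constraint-violating parameters."""
        if np.any(self.w_h2 < 0):
            raise ConstraintError("w_h2 must be elementwise non-negative")
        if np.any(self.w_final < 0):
            raise ConstraintError("w_final must be non-negative")

    def project(self) -> None:
        """Clip the constrained weights at zero (used after optimizer steps)."""
        np.maximum(self.w_h2, 0.0, out=self.w_h2)
        np.maximum(self.w_final, 0.0, out=self.w_final)


def init_head_params(
    rng: np.random.Generator, n_slots: int, l2_strength: float = 1e-4,
    scale_h1: float = 0.1, scale_h2: float = 0.1,
    final_low: float = 15.0, final_high: float = 30.0,
) -> EnergyHeadParams:
    """Random initialisation.

    ``scale_h1``/``scale_h2`` should be chosen so the sigmoid preactivations
    start near unit variance (the trainer derives them from the GNN output
    magnitudes); saturated sigmoids at initialisation kill the gradient of
    the constrained head.  The final-layer scales start in the band of
    experimentally accessible barriers (solution kinetics on second-to-hour
    timescales corresponds to roughly 15-30 kcal/mol at room temperature)
    so the first-stage energy regression starts within a few kcal/mol of
    typical barriers.
    """
    return EnergyHeadParams(
        w_h1=rng.normal(0.0, scale_h1, size=2 + n_slots),
        w_h2=np.abs(rng.normal(0.0, scale_h2, size=n_slots)),
        w_final=rng.uniform(final_low, final_high, size=2),
        l2_strength=l2_strength,
    )


@dataclass(frozen=True)
class EnergyDecomposition:
    """Predicted barrier of one reaction, split into its two components."""

    dG_L: float
    dG_LS: float
    dG_total: float
    k_pred: float
    T: float


def _sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def forward_batch(
    gnn_out: np.ndarray,
    hammett: np.ndarray,
    params: EnergyHeadParams,
    temperature_K,
    keep_cache: bool = False,
):
    """Vectorized head forward pass.

    gnn_out: (B, S); hammett: (B, 2).  Returns a dict with per-reaction
    arrays dG_L, dG_LS, dG_total, k_pred (and a cache when requested).
    """
    params.validate()
    gnn_out = np.atleast_2d(np.asarray(gnn_out, dtype=float))
    hammett = np.atleast_2d(np.asarray(hammett, dtype=float))
    x1 = np.concatenate([hammett, gnn_out], axis=1)
    z1 = x1 @ params.w_h1
    z2 = gnn_out @ params.w_h2
    h_ls = _sigmoid(z1)
    h_l = _sigmoid(z2)
    dG_LS = params.w_final[0] * h_ls
    dG_L = params.w_final[1] * h_l
    dG = dG_LS + dG_L
    k = eyring_rate_from_energy(dG, temperature_K)
    out = {"dG_L": dG_L, "dG_LS": dG_LS, "dG_total": dG, "k_pred": k}
    if keep_cache:
        out["cache"] = (gnn_out, x1, h_ls, h_l)
    return out


def backward_batch(d_dG: np.ndarray, cache, params: EnergyHeadParams):
    """Head gradients given d(loss)/d(dG_total) per reaction.

    Returns (d_w_h1, d_w_h2, d_w_final, d_gnn_out); L2 penalty terms are
    added by the caller.
    """
    gnn_out, x1, h_ls, h_l = cache
    d_dG = np.asarray(d_dG, dtype=float)
    d_wf = np.array([d_dG @ h_ls, d_dG @ h_l])
    ds1 = params.w_final[0] * d_dG * h_ls * (1.0 - h_ls)
    ds2 = params.w_final[1] * d_dG * h_l * (1.0 - h_l)
    d_w_h1 = x1.T @ ds1
    d_w_h2 = gnn_out.T @ ds2
    d_gnn = np.outer(ds1, params.w_h1[2:]) + np.outer(ds2, params.w_h2)
    return d_w_h1, d_w_h2, d_wf, d_gnn


def forward(
    gnn_out: np.ndarray,
    hammett: HammettVector,
    params: EnergyHeadParams,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> EnergyDecomposition:
    """Single-reaction prediction with exact additive decomposition."""
    res = forward_batch(
        gnn_out, np.array([[hammett.sigma_meta, hammett.sigma_para]]),
        params, temperature_K,
    )
    return EnergyDecomposition(
        dG_L=float(res["dG_L"][0]),
        dG_LS=float(res["dG_LS"][0]),
        dG_total=float(res["dG_LS"][0]) + float(res["dG_L"][0]),
        k_pred=float(res["k_pred"][0]),
        T=float(temperature_K),
    )
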