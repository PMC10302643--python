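"""Two-stage training protocol, model selection, ensembling and CV.

Training follows the bespoke schedule of the original protocol: batches of
10 reactions, Adam, MAE loss, up to 10,000 epochs.  In stage 1 the network
regresses predicted activation energies against the Eyring-converted
experimental energies until a batch MAE drops below the stage cutoff
(5-7 kcal/mol); the remaining epochs form stage 2, which regresses
predicted rate constants against the experimental ones for finer
optimisation.  Rate-space losses are computed on rates normalised by the
maximum training-set rate so that the loss is a bounded dimensionless
number and the fixed fluctuation/convergence thresholds (0.2 / 1e-4) are
meaningful regardless of the units k is reported in.

A per-batch termination rule watches the trailing window of batch losses:
if >= 80% of consecutive loss changes flip sign and their mean magnitude
exceeds 0.2 the run is rejected as fluctuating; if the mean magnitude falls
below 1e-4 the run has converged and stops early.

Runs whose validation R^2 (rate space) exceeds 0.8 and validation MAE
(normalised rate space) stays below 1.5 qualify for the ensemble; the up to
10 qualifiers with the largest validation R^2 are kept, and the ensemble
prediction is the arithmetic mean of member predictions (rates averaged in
rate space, energy components averaged alongside for reporting).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .energy import (
    DEFAULT_TEMPERATURE_K,
    GAS_CONSTANT_KCAL,
    EnergyHeadParams,
    backward_batch,
    eyring_energy_from_rate,
    forward_batch,
    init_head_params,
)
from .errors import EmptyEnsembleError
from .ligand_tree import LigandTree, build_template, canonicalize, encode_graph
from .mpnn import GraphBatch, MpnnParams, init_mpnn_params
from .substrate import HammettTable, encode_substrate, load_hammett_table

CONTINUE = "continue"
CONVERGED = "converged"
REJECTED = "rejected"

STATUS_COMPLETED = "completed"
STATUS_CONVERGED = "converged_early"
STATUS_REJECTED = "rejected_fluctuation"

LEARNING_RATE_GRID = (0.0005, 0.001, 0.002, 0.005)
MESSAGE_DIM_GRID = (2, 3, 4)
ITERATION_GRID = (3, 4, 5)
STAGE1_CUTOFF_GRID = (5.0, 6.0, 7.0)


@dataclass
class TrainConfig:
    """Hyperparameters and protocol constants for one training run."""

    learning_rate: float = 0.002
    d_m: int = 3
    iterations: int = 4
    batch_size: int = 10
    max_epochs: int = 10_000
    stage1_cutoff: float = 6.0  # kcal/mol, batch MAE ending stage 1
    fluct_window: int = 10  # number of trailing loss changes inspected
    fluct_sign_frac: float = 0.8
    fluct_mag: float = 0.2
    converge_tol: float = 1e-4
    seed: int = 0
    T: float = DEFAULT_TEMPERATURE_K
    l2_strength: float = 1e-4

    def validate_grid(self) -> None:
        if self.learning_rate not in LEARNING_RATE_GRID:
            raise ValueError(f"learning_rate outside grid {LEARNING_RATE_GRID}")
        if self.d_m not in MESSAGE_DIM_GRID:
            raise ValueError(f"d_m outside grid {MESSAGE_DIM_GRID}")
        if self.iterations not in ITERATION_GRID:
            raise ValueError(f"iterations outside grid {ITERATION_GRID}")


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class ReactionDataset:
    """Reactions plus encoded ligand structures, ready for training.

    ``graph_batch`` holds the aligned graphs of all ligands (MPNN path);
    ``ligand_features`` holds static per-ligand descriptor vectors instead
    (baseline path).  Exactly one of the two is set.
    """

    reactions: pd.DataFrame
    ligand_ids: list[str]
    lig_idx: np.ndarray  # (N,) index into ligand_ids per reaction
    hammett: np.ndarray  # (N, 2)
    k_obs: np.ndarray  # (N,)
    dG_obs: np.ndarray  # (N,) Eyring-converted, kcal/mol
    temps: np.ndarray  # (N,) kelvin
    graph_batch: GraphBatch | None = None
    ligand_features: np.ndarray | None = None
    trees: dict[str, LigandTree] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.reactions)

    @property
    def n_slots(self) -> int:
        if self.graph_batch is not None:
            return self.graph_batch.n_slots
        return self.ligand_features.shape[1]

    def ligand_matrix(self, mpnn: MpnnParams | None, keep_cache: bool = False):
        if self.graph_batch is not None:
            return self.graph_batch.forward(mpnn, keep_cache=keep_cache)
        if keep_cache:
            return self.ligand_features, None
        return self.ligand_features

    def subset(self, indices) -> "ReactionDataset":
        indices = np.asarray(indices)
        return ReactionDataset(
            reactions=self.reactions.iloc[indices].reset_index(drop=True),
            ligand_ids=self.ligand_ids,
            lig_idx=self.lig_idx[indices],
            hammett=self.hammett[indices],
            k_obs=self.k_obs[indices],
            dG_obs=self.dG_obs[indices],
            temps=self.temps[indices],
            graph_batch=self.graph_batch,
            ligand_features=self.ligand_features,
            trees=self.trees,
        )


def _reaction_arrays(reactions: pd.DataFrame, ligand_ids, table: HammettTable):
    id_pos = {lid: i for i, lid in enumerate(ligand_ids)}
    lig_idx = reactions["ligand_id"].map(id_pos)
    if lig_idx.isna().any():
        missing = sorted(set(reactions.loc[lig_idx.isna(), "ligand_id"]))
        raise ValueError(f"reactions reference unknown ligands: {missing}")
    hv = [
        encode_substrate(sub, pos, table)
        for sub, pos in zip(reactions["substituent"], reactions["position"])
    ]
    hammett = np.array(hv, dtype=float)
    k_obs = reactions["k_obs"].to_numpy(dtype=float)
    temps = reactions["temperature_K"].to_numpy(dtype=float)
    dG_obs = np.asarray(eyring_energy_from_rate(k_obs, temps))
    return np.asarray(lig_idx, dtype=np.intp), hammett, k_obs, dG_obs, temps


def build_dataset(
    reactions: pd.DataFrame,
    ligand_trees: Sequence[LigandTree],
    hammett_table: HammettTable | None = None,
    template=None,
) -> ReactionDataset:
    """Encode ligand trees and substrate vectors for a reaction table."""
    table = hammett_table or load_hammett_table()
    trees = {t.name: canonicalize(t) if not t.is_canonical else t for t in ligand_trees}
    template = template or build_template(trees.values())
    ligand_ids = list(trees)
    graphs = [encode_graph(trees[lid], template) for lid in ligand_ids]
    lig_idx, hammett, k_obs, dG_obs, temps = _reaction_arrays(
        reactions, ligand_ids, table
    )
    return ReactionDataset(
        reactions=reactions.reset_index(drop=True),
        ligand_ids=ligand_ids,
        lig_idx=lig_idx,
        hammett=hammett,
        k_obs=k_obs,
        dG_obs=dG_obs,
        temps=temps,
        graph_batch=GraphBatch(graphs),
        trees=trees,
    )


def build_feature_dataset(
    reactions: pd.DataFrame,
    feature_table: pd.DataFrame,
    hammett_table: HammettTable | None = None,
) -> ReactionDataset:
    """Dataset whose ligand representation is a static descriptor vector.

    ``feature_table`` is indexed by ligand id (see `baselines`); the
    substrate (Hammett) pathway is identical to the graph dataset.
    """
    table = hammett_table or load_hammett_table()
    ligand_ids = list(feature_table.index)
    lig_idx, hammett, k_obs, dG_obs, temps = _reaction_arrays(
        reactions, ligand_ids, table
    )
    return ReactionDataset(
        reactions=reactions.reset_index(drop=True),
        ligand_ids=ligand_ids,
        lig_idx=lig_idx,
        hammett=hammett,
        k_obs=k_obs,
        dG_obs=dG_obs,
        temps=temps,
        ligand_features=feature_table.to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# splitting


def split_indices(n: int, fractions=(0.6, 0.2, 0.2), seed: int = 0):
    """Random disjoint (train, val, test) index partition.

    Sizes: round(f_train * n) and round(f_val * n); the test split takes the
    remainder, so the three always partition range(n).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if n < 5:
        raise ValueError(f"dataset of size {n} is too small to split (need >= 5)")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = round(fractions[0] * n)
    n_val = round(fractions[1] * n)
    return perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:]


def split_dataset(dataset: ReactionDataset, fractions=(0.6, 0.2, 0.2), seed: int = 0):
    tr, va, te = split_indices(len(dataset), fractions, seed)
    return dataset.subset(tr), dataset.subset(va), dataset.subset(te)


# ---------------------------------------------------------------------------
# termination rule


def check_termination(recent_losses: Sequence[float], config: TrainConfig) -> str:
    """Classify the trailing loss window as continue / converged / rejected.

    Inspects the last ``fluct_window`` consecutive batch-loss changes.  The
    run is rejected when at least ``fluct_sign_frac`` of adjacent change
    pairs flip sign AND the mean |change| exceeds ``fluct_mag``; it has
    converged when the mean |change| drops below ``converge_tol``.  Pure
    function of its window; with fewer than fluct_window + 1 losses the
    answer is always ``continue``.
    """
    w = config.fluct_window
    losses = np.asarray(list(recent_losses)[-(w + 1):], dtype=float)
    if losses.size < w + 1:
        return CONTINUE
    changes = np.diff(losses)
    mean_abs = float(np.mean(np.abs(changes)))
    n_pairs = changes.size - 1
    flips = int(np.sum(changes[1:] * changes[:-1] < 0))
    if n_pairs > 0 and flips / n_pairs >= config.fluct_sign_frac and (
        mean_abs > config.fluct_mag
    ):
        return REJECTED
    if mean_abs < config.converge_tol:
        return CONVERGED
    return CONTINUE


# ---------------------------------------------------------------------------
# model, optimizer, training loop


@dataclass
class Model:
    """Trainable parameters plus the rate normalisation constant."""

    mpnn: MpnnParams | None
    head: EnergyHeadParams
    k_scale: float = 1.0


def predict(model: Model, dataset: ReactionDataset) -> pd.DataFrame:
    """Per-reaction predictions (dG_L, dG_LS, dG_total, k_pred)."""
    g_all = dataset.ligand_matrix(model.mpnn)
    res = forward_batch(
        g_all[dataset.lig_idx], dataset.hammett, model.head, dataset.temps
    )
    out = dataset.reactions.copy()
    for col in ("dG_L", "dG_LS", "dG_total", "k_pred"):
        out[col] = res[col]
    return out


class _Adam:
    def __init__(self, arrays, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, arrays, grads):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for a, g, m, v in zip(arrays, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            a -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


@dataclass
class TrainRunResult:
    model: Model
    loss_history: list  # (stage, batch loss) per optimizer step
    termination_status: str
    val_r2: float
    val_mae: float
    stage1_cutoff_reached: bool
    config: TrainConfig


def r2_score(y_true, y_pred) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot


def _model_arrays(model: Model):
    arrays = []
    if model.mpnn is not None:
        arrays += [model.mpnn.w_message, model.mpnn.w_update]
    arrays += [model.head.w_h1, model.head.w_h2, model.head.w_final]
    return arrays


def _train_step(model: Model, ds: ReactionDataset, idx, stage: int, adam: _Adam):
    head = model.head
    g_all, g_cache = ds.ligand_matrix(model.mpnn, keep_cache=True)
    li = ds.lig_idx[idx]
    res = forward_batch(
        g_all[li], ds.hammett[idx], head, ds.temps[idx], keep_cache=True
    )
    if stage == 1:
        r = res["dG_total"] - ds.dG_obs[idx]
        loss_data = float(np.mean(np.abs(r)))
        d_dG = np.sign(r) / r.size
    else:
        k_pred = res["k_pred"] / model.k_scale
        r = k_pred - ds.k_obs[idx] / model.k_scale
        loss_data = float(np.mean(np.abs(r)))
        # chain rule through k = A exp(-dG/RT): dk/ddG = -k/(RT)
        d_dG = np.sign(r) / r.size * (-k_pred / (GAS_CONSTANT_KCAL * ds.temps[idx]))
    d_wh1, d_wh2, d_wf, d_g = backward_batch(d_dG, res["cache"], head)
    l2 = head.l2_strength
    loss = loss_data + l2 * (head.w_h1 @ head.w_h1 + head.w_h2 @ head.w_h2)
    d_wh1 += 2.0 * l2 * head.w_h1
    d_wh2 += 2.0 * l2 * head.w_h2
    grads = [d_wh1, d_wh2, d_wf]
    if model.mpnn is not None:
        d_g_all = np.zeros_like(g_all)
        np.add.at(d_g_all, li, d_g)
        d_wm, d_wu = ds.graph_batch.backward(d_g_all, g_cache, model.mpnn)
        grads = [d_wm, d_wu] + grads
    adam.step(_model_arrays(model), grads)
    head.project()
    return loss


def evaluate(model: Model, dataset: ReactionDataset) -> tuple[float, float]:
    """(R^2 in rate space, MAE in normalised rate space)."""
    pred = predict(model, dataset)
    r2 = r2_score(dataset.k_obs, pred["k_pred"])
    mae = float(np.mean(np.abs(pred["k_pred"] - dataset.k_obs))) / model.k_scale
    return r2, mae


def _steric_ramp_target(train_ds: ReactionDataset) -> np.ndarray | None:
    """Descending per-ligand sigmoid preactivation target (bulk-ordered)."""
    if not train_ds.trees:
        return None
    steric = np.array(
        [train_ds.trees[lid].steric_proxy() for lid in train_ds.ligand_ids],
        dtype=float,
    )
    if steric.std() == 0:
        return None
    # centred inside the active sigmoid range; bulkier ligand -> lower z
    return 1.0 - (steric - steric.mean()) / steric.std()


def _draw_mpnn_init(
    train_ds: ReactionDataset, config: TrainConfig, rng: np.random.Generator,
    max_draws: int = 200,
):
    """Draw MPNN weights whose output admits the mechanistic orientation.

    Bias-free LeakyReLU recursions can collapse all states to ~0 for
    unlucky draws, and most draws produce slot states whose non-negative
    readouts only *increase* with ligand bulk.  Because the barrier split
    is weakly identified (see `_orient_head_init`), the initial weight draw
    is accepted only if a non-negative readout of its output can realise a
    descending steric ramp; otherwise the best of ``max_draws`` redraws is
    kept.  All draws derive from the run's seed.
    """
    target = _steric_ramp_target(train_ds)
    best = None
    for _ in range(max_draws):
        mpnn = init_mpnn_params(rng, config.d_m, config.iterations, scale=0.3)
        g_all = train_ds.ligand_matrix(mpnn)
        if np.sqrt(np.mean(g_all**2)) <= 1e-2:
            continue  # collapsed states
        if target is None:
            return mpnn, g_all
        w2, _ = scipy.optimize.nnls(g_all, target)
        z2 = g_all @ w2
        corr = np.corrcoef(z2, target)[0, 1] if z2.std() > 1e-9 else -1.0
        if best is None or corr > best[2]:
            best = (mpnn, g_all, corr)
        if corr > 0.9:
            break
    if best is None:  # pathological: everything collapsed
        mpnn = init_mpnn_params(rng, config.d_m, config.iterations, scale=0.3)
        return mpnn, train_ds.ligand_matrix(mpnn)
    return best[0], best[1]


def _orient_head_init(
    head: EnergyHeadParams, train_ds: ReactionDataset, g_all: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Mechanism-informed orientation of the head initialisation.

    The split of the barrier into a ligand-only and a ligand-substrate part
    is only weakly identified by rate data: any ligand-dependent shift can
    be moved between the two heads without changing the total.  Training
    largely preserves whatever per-ligand trend each head starts with, so
    the degenerate direction is oriented here by mechanistic knowledge
    rather than left to chance:

    * the ligand-only head is initialised as a *descending steric ramp* —
      bulky phosphines are known to accelerate oxidative addition, so its
      sigmoid preactivation is fit (non-negative least squares, respecting
      the w_h2 >= 0 constraint) to decrease with the ligand's node count
      near phosphorus;
    * the cooperative head starts with no ligand pathway (those weights at
      0) and negative Hammett weights — electron-withdrawing substituents
      lower the barrier.

    These are starting points only; every weight remains free to train.
    """
    head.w_h1[:2] = -np.abs(head.w_h1[:2])
    if train_ds.graph_batch is None:
        return
    target = _steric_ramp_target(train_ds)
    if target is None:
        return
    w2, _ = scipy.optimize.nnls(g_all, target)
    z2 = g_all @ w2
    if z2.std() <= 1e-6 or np.corrcoef(z2, target)[0, 1] <= 0.3:
        return
    head.w_h2 = w2
    head.w_h1[2:] = 0.0

    # moment-match the heads to the training energies so rate-space
    # fine-tuning starts from a calm, mechanistically oriented state:
    # ligand head <- per-ligand mean barrier, cooperative head <- substrate
    # residual through the Hammett weights
    h_l = 1.0 / (1.0 + np.exp(-z2))  # per-ligand
    y_lig = np.zeros(len(train_ds.ligand_ids))
    for j in range(len(y_lig)):
        rows = train_ds.lig_idx == j
        y_lig[j] = train_ds.dG_obs[rows].mean() if rows.any() else np.nan
    ok = np.isfinite(y_lig)
    if ok.sum() >= 2 and np.ptp(h_l[ok]) > 1e-9:
        slope = np.polyfit(h_l[ok], y_lig[ok], 1)[0]
        head.w_final[1] = float(np.clip(slope, 1.0, 40.0))
    resid = train_ds.dG_obs - head.w_final[1] * h_l[train_ds.lig_idx]
    head.w_final[0] = float(np.clip(2.0 * resid.mean(), 1.0, 60.0))
    h_t = np.clip(resid / head.w_final[0], 0.05, 0.95)
    z1_t = np.log(h_t / (1.0 - h_t))
    wsig, *_ = np.linalg.lstsq(train_ds.hammett, z1_t, rcond=None)
    head.w_h1[:2] = wsig


def train_two_stage(
    train_ds: ReactionDataset, val_ds: ReactionDataset, config: TrainConfig
) -> TrainRunResult:
    """Run the two-stage protocol on one (train, val) pair."""
    rng = np.random.default_rng(config.seed)
    mpnn = None
    g_all = train_ds.ligand_matrix(None) if train_ds.graph_batch is None else None
    if train_ds.graph_batch is not None:
        mpnn, g_all = _draw_mpnn_init(train_ds, config, rng)
    # variance-scaled head init: aim for unit-variance sigmoid preactivations
    # under the actual ligand feature magnitudes, so neither head starts
    # saturated (which would freeze its gradient)
    g_rows = g_all[train_ds.lig_idx]
    x1_rows = np.concatenate([train_ds.hammett, g_rows], axis=1)
    s1 = min(1.0 / max(np.sqrt(np.mean(np.sum(x1_rows**2, axis=1))), 1e-8), 10.0)
    s2 = min(1.0 / max(np.sqrt(np.mean(np.sum(g_rows**2, axis=1))), 1e-8), 10.0)
    head = init_head_params(
        rng, train_ds.n_slots, l2_strength=config.l2_strength,
        scale_h1=s1, scale_h2=s2,
    )
    _orient_head_init(head, train_ds, g_all, rng)
    # calibrate the output scales so the initial mean barrier matches the
    # training mean (output-layer mean initialisation); the first-stage
    # regression then starts from a physically sensible baseline
    init_dG = forward_batch(g_rows, train_ds.hammett, head, train_ds.temps)["dG_total"]
    mean_pred = float(np.mean(init_dG))
    if mean_pred > 1e-8:
        head.w_final *= float(np.mean(train_ds.dG_obs)) / mean_pred
    # rates are normalised to unit maximum so rate-space losses are O(1)
    # dimensionless numbers whatever units k_obs arrives in
    model = Model(mpnn=mpnn, head=head, k_scale=float(np.max(train_ds.k_obs)))

    adam = _Adam(_model_arrays(model), config.learning_rate)
    stage = 1
    stage1_reached = False
    status = STATUS_COMPLETED
    history: list[tuple[int, float]] = []
    window: list[float] = []
    n = len(train_ds)
    bs = config.batch_size

    # incomplete trailing batches are dropped (all samples still cycle via
    # reshuffling): a periodically smaller batch produces an alternating
    # loss pattern the fluctuation rule would misread as divergence
    n_batches = max(n // bs, 1)
    for _epoch in range(config.max_epochs):
        perm = rng.permutation(n)
        verdict = CONTINUE
        for b in range(n_batches):
            idx = perm[b * bs:(b + 1) * bs]
            loss = _train_step(model, train_ds, idx, stage, adam)
            history.append((stage, loss))
            window.append(loss)
            verdict = check_termination(window, config)
            if verdict != CONTINUE:
                break
            if stage == 1 and loss < config.stage1_cutoff:
                # batch loss under the cutoff ends stage 1: switch to
                # rate-space fine-tuning; the loss landscape changes, so
                # optimizer state and the termination window start afresh
                stage = 2
                stage1_reached = True
                adam = _Adam(_model_arrays(model), config.learning_rate)
                window = []
        if verdict == REJECTED:
            status = STATUS_REJECTED
            break
        if verdict == CONVERGED:
            status = STATUS_CONVERGED
            break

    val_r2, val_mae = evaluate(model, val_ds)
    return TrainRunResult(
        model=model,
        loss_history=history,
        termination_status=status,
        val_r2=val_r2,
        val_mae=val_mae,
        stage1_cutoff_reached=stage1_reached,
        config=config,
    )


# ---------------------------------------------------------------------------
# selection & ensembling


@dataclass
class Ensemble:
    """Up to 10 selected runs whose averaged predictions are the output."""

    members: list[TrainRunResult]
    r2_threshold: float = 0.8
    mae_threshold: float = 1.5

    def __post_init__(self):
        if not self.members:
            raise EmptyEnsembleError("ensemble needs at least one member")
        for m in self.members:
            if not (m.val_r2 > self.r2_threshold and m.val_mae < self.mae_threshold):
                raise EmptyEnsembleError(
                    "ensemble member violates selection thresholds "
                    f"(val_r2={m.val_r2:.3f}, val_mae={m.val_mae:.3f})"
                )

    def __len__(self) -> int:
        return len(self.members)

    def member_predictions(self, dataset: ReactionDataset) -> list[pd.DataFrame]:
        return [predict(m.model, dataset) for m in self.members]

    def predict(self, dataset: ReactionDataset) -> pd.DataFrame:
        """Arithmetic mean of member predictions (rates in rate space)."""
        preds = self.member_predictions(dataset)
        out = dataset.reactions.copy()
        for col in ("dG_L", "dG_LS", "dG_total", "k_pred"):
            out[col] = np.mean([p[col].to_numpy() for p in preds], axis=0)
        return out


def select_and_ensemble(
    results: Sequence[TrainRunResult],
    r2_threshold: float = 0.8,
    mae_threshold: float = 1.5,
    max_members: int = 10,
) -> Ensemble:
    """Filter by validation thresholds and keep the top runs by val R^2.

    Runs rejected for loss fluctuation never qualify.
    """
    qualifiers = [
        r
        for r in results
        if r.termination_status != STATUS_REJECTED
        and r.val_r2 > r2_threshold
        and r.val_mae < mae_threshold
    ]
    if not qualifiers:
        raise EmptyEnsembleError(
            f"no run met val_r2 > {r2_threshold} and val_mae < {mae_threshold}; "
            "run more trials or widen the hyperparameter search"
        )
    qualifiers.sort(key=lambda r: r.val_r2, reverse=True)
    return Ensemble(
        members=qualifiers[:max_members],
        r2_threshold=r2_threshold,
        mae_threshold=mae_threshold,
    )


# ---------------------------------------------------------------------------
# cross-validation


def make_cv_folds(n: int, n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Equal-sized random fold labels 0..n_folds-1; label n_folds-1 is the
    fixed test fold."""
    if n < n_folds:
        raise ValueError("dataset smaller than the number of folds")
    perm = np.random.default_rng(seed).permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        folds[chunk] = f
    return folds


def cross_validate(
    dataset: ReactionDataset,
    config: TrainConfig,
    n_folds: int = 5,
    seed: int = 0,
    n_trials: int = 1,
) -> pd.DataFrame:
    """Fixed-test-fold cross-validation.

    The last fold is the test set in every run; run j (j = 0..n_folds-2)
    uses fold j for validation and the remaining folds for training.  Each
    run trains ``n_trials`` seeds and ensembles the qualifiers (falling back
    to the best single run when none qualify).
    """
    folds = make_cv_folds(len(dataset), n_folds, seed)
    test_fold = n_folds - 1
    test_ds = dataset.subset(np.flatnonzero(folds == test_fold))
    records = []
    for run, val_fold in enumerate(range(n_folds - 1)):
        train_mask = (folds != val_fold) & (folds != test_fold)
        train_ds = dataset.subset(np.flatnonzero(train_mask))
        val_ds = dataset.subset(np.flatnonzero(folds == val_fold))
        results = [
            train_two_stage(
                train_ds, val_ds,
                replace(config, seed=(config.seed * 1009 + 7919 * run + t) % 2**31),
            )
            for t in range(n_trials)
        ]
        try:
            ens = select_and_ensemble(results)
            val_pred = ens.predict(val_ds)["k_pred"]
            test_pred = ens.predict(test_ds)["k_pred"]
            n_members = len(ens)
        except EmptyEnsembleError:
            best = max(results, key=lambda r: r.val_r2)
            val_pred = predict(best.model, val_ds)["k_pred"]
            test_pred = predict(best.model, test_ds)["k_pred"]
            n_members = 0
        records.append(
            {
                "run": run + 1,
                "val_fold": val_fold,
                "test_fold": test_fold,
                "n_members": n_members,
                "val_r2": r2_score(val_ds.k_obs, val_pred),
                "test_r2": r2_score(test_ds.k_obs, test_pred),
            }
        )
    df = pd.DataFrame.from_records(records)
    df.attrs["folds"] = folds
    df.attrs["mean_val_r2"] = float(df["val_r2"].mean())
    df.attrs["mean_test_r2"] = float(df["test_r2"].mean())
    return df


# ---------------------------------------------------------------------------
# hyperparameter search


DEFAULT_SEARCH_SPACE = {
    "learning_rate": LEARNING_RATE_GRID,
    "d_m": MESSAGE_DIM_GRID,
    "iterations": ITERATION_GRID,
    "stage1_cutoff": STAGE1_CUTOFF_GRID,
}


def tune_hyperparameters(
    train_ds: ReactionDataset,
    val_ds: ReactionDataset,
    space: dict | None = None,
    budget: int = 12,
    seed: int = 0,
    base_config: TrainConfig | None = None,
):
    """Random search over the hyperparameter grid, scored by validation R^2.

    Returns (best TrainConfig, trial log DataFrame).  Each grid point is
    trained at most once (a one-point space with any budget trains once).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    space = space or DEFAULT_SEARCH_SPACE
    base = base_config or TrainConfig()
    names = list(space)
    grid = list(itertools.product(*(space[k] for k in names)))
    rng = np.random.default_rng(seed)
    if budget < len(grid):
        chosen = [grid[i] for i in rng.choice(len(grid), size=budget, replace=False)]
    else:
        chosen = grid
    records = []
    best = None
    for trial, point in enumerate(chosen):
        cfg = replace(
            base,
            **dict(zip(names, point)),
            seed=(seed * 1009 + trial) % 2**31,
        )
        result = train_two_stage(train_ds, val_ds, cfg)
        records.append(
            {
                "trial": trial,
                **dict(zip(names, point)),
                "status": result.termination_status,
                "val_r2": result.val_r2,
                "val_mae": result.val_mae,
            }
        )
        if best is None or (
            np.nan_to_num(result.val_r2, nan=-np.inf)
            > np.nan_to_num(best[1].val_r2, nan=-np.inf)
        ):
            best = (cfg, result)
    return best[0], pd.DataFrame.from_records(records)
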