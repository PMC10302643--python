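"""JSON (de)serialization of trained models and ensembles.

Parameters are stored as a flat named-array archive in JSON: small models,
human-inspectable artifacts, no binary formats.  The graph template's slot
paths are stored alongside so unseen reaction tables are encoded with the
exact training layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .energy import EnergyHeadParams
from .ligand_tree import GraphTemplate
from .mpnn import MpnnParams
from .training import Ensemble, Model, TrainConfig, TrainRunResult


def _model_to_dict(model: Model) -> dict:
    d = {
        "w_h1": model.head.w_h1.tolist(),
        "w_h2": model.head.w_h2.tolist(),
        "w_final": model.head.w_final.tolist(),
        "l2_strength": model.head.l2_strength,
        "k_scale": model.k_scale,
    }
    if model.mpnn is not None:
        d["w_message"] = model.mpnn.w_message.tolist()
        d["w_update"] = model.mpnn.w_update.tolist()
        d["iterations"] = model.mpnn.iterations
        d["leaky_slope"] = model.mpnn.leaky_slope
    return d


def _model_from_dict(d: dict) -> Model:
    mpnn = None
    if "w_message" in d:
        mpnn = MpnnParams(
            w_message=np.array(d["w_message"]),
            w_update=np.array(d["w_update"]),
            iterations=int(d["iterations"]),
            leaky_slope=float(d["leaky_slope"]),
        )
    head = EnergyHeadParams(
        w_h1=np.array(d["w_h1"]),
        w_h2=np.array(d["w_h2"]),
        w_final=np.array(d["w_final"]),
        l2_strength=float(d["l2_strength"]),
    )
    return Model(mpnn=mpnn, head=head, k_scale=float(d["k_scale"]))


def save_ensemble(
    ensemble: Ensemble, path: str | Path, template: GraphTemplate | None = None
) -> None:
    payload = {
        "r2_threshold": ensemble.r2_threshold,
        "mae_threshold": ensemble.mae_threshold,
        "members": [
            {
                **_model_to_dict(m.model),
                "val_r2": m.val_r2,
                "val_mae": m.val_mae,
                "termination_status": m.termination_status,
            }
            for m in ensemble.members
        ],
    }
    if template is not None:
        payload["template_paths"] = [list(p) for p in template.paths]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_ensemble(path: str | Path) -> tuple[Ensemble, GraphTemplate | None]:
    with open(path) as fh:
        payload = json.load(fh)
    members = [
        TrainRunResult(
            model=_model_from_dict(d),
            loss_history=[],
            termination_status=d.get("termination_status", "completed"),
            val_r2=float(d["val_r2"]),
            val_mae=float(d["val_mae"]),
            stage1_cutoff_reached=True,
            config=TrainConfig(),
        )
        for d in payload["members"]
    ]
    ensemble = Ensemble(
        members=members,
        r2_threshold=float(payload["r2_threshold"]),
        mae_threshold=float(payload["mae_threshold"]),
    )
    template = None
    if "template_paths" in payload:
        template = GraphTemplate(
            paths=tuple(tuple(p) for p in payload["template_paths"])
        )
    return ensemble, template
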