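"""Trial-container and model-checkpoint persistence.

Trials travel as compressed numpy archives (`.npz`) with the fields
``data`` (R×Nc×Nt), ``labels``, ``fs``, ``channel_names``, ``cue_onset``
and optionally ``channel_positions`` — a language-neutral container with no
EEG-format dependency.  Model checkpoints are a single archive holding the
parameter arrays, running normalisation statistics and the estimator
configuration.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .containers import EEGTrialSet
from .model import KCSFCnet

__all__ = ["read_trials", "write_trials", "save_model", "load_model"]

log = logging.getLogger("kcsfcnet")

_REQUIRED = ("data", "labels", "fs")


def write_trials(path: str | Path, trials: EEGTrialSet) -> Path:
    """Write an :class:`EEGTrialSet` to a compressed array archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(
        data=trials.data,
        labels=trials.labels,
        fs=np.asarray(trials.fs),
        channel_names=np.asarray(trials.channel_names),
        cue_onset=np.asarray(trials.cue_onset),
    )
    if trials.channel_positions is not None:
        payload["channel_positions"] = trials.channel_positions
    np.savez_compressed(path, **payload)
    return path


def read_trials(path: str | Path) -> EEGTrialSet:
    """Load and validate a trial archive written by :func:`write_trials`.

    Labels are coerced to {0, 1}: exactly two distinct values are mapped in
    sorted order (the class map is logged); anything else is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path, allow_pickle=False) as archive:
        for fieldname in _REQUIRED:
            if fieldname not in archive:
                raise ValueError(f"trial file {path} is missing field {fieldname!r}")
        data = archive["data"]
        labels = archive["labels"]
        fs = float(archive["fs"])
        names = [str(n) for n in archive["channel_names"]] if "channel_names" in archive else []
        cue = float(archive["cue_onset"]) if "cue_onset" in archive else 0.0
        pos = archive["channel_positions"] if "channel_positions" in archive else None

    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"labels must have exactly 2 classes, found {uniq.tolist()}")
    if set(uniq.tolist()) != {0, 1}:
        mapping = {v: k for k, v in enumerate(sorted(uniq.tolist()))}
        log.info("coercing labels to 0/1 with class map %s", mapping)
        labels = np.array([mapping[v] for v in labels.tolist()])
    if not np.all(np.isfinite(data)):
        bad = np.unique(np.argwhere(~np.isfinite(data))[:, 0]).tolist()
        raise ValueError(f"non-finite data in trials {bad} of {path}")

    return EEGTrialSet(data=data, labels=labels, fs=fs, channel_names=names,
                       channel_positions=pos, cue_onset=cue)


def save_model(path: str | Path, model: KCSFCnet) -> Path:
    """Checkpoint a fitted model: parameters, running stats, config, classes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {f"param_{k}": np.asarray(v) for k, v in model._params.items()}
    if model.batch_norm:
        payload.update(
            run_mu1=np.asarray(model._run_mu1), run_var1=np.asarray(model._run_var1),
            run_mu2=np.asarray(model._run_mu2), run_var2=np.asarray(model._run_var2),
        )
    payload["classes"] = model.classes_
    payload["shape"] = np.array([model._nc, model._nt])
    payload["config_json"] = np.frombuffer(
        json.dumps(model.get_params(), sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **payload)
    return path


def load_model(path: str | Path) -> KCSFCnet:
    """Restore a checkpointed model ready for inference."""
    path = Path(path)
    with np.load(path, allow_pickle=False) as archive:
        config = json.loads(bytes(archive["config_json"]).decode())
        model = KCSFCnet(**config)
        params = {k[len("param_"):]: np.asarray(archive[k])
                  for k in archive.files if k.startswith("param_")}
        nc, nt = (int(v) for v in archive["shape"])
        model._nc, model._nt = nc, nt
        model._m = nc * (nc - 1) // 2
        from .model import pair_indices, count_parameters

        model._pair_i, model._pair_j = pair_indices(nc)
        ftype = params["W"].dtype
        S = np.zeros((nc, model._m), dtype=ftype)
        S[model._pair_i, np.arange(model._m)] = 1.0
        S[model._pair_j, np.arange(model._m)] = -1.0
        model._incidence = S
        if model.batch_norm:
            model._run_mu1 = np.asarray(archive["run_mu1"])
            model._run_var1 = np.asarray(archive["run_var1"])
            model._run_mu2 = ftype.type(archive["run_mu2"])
            model._run_var2 = ftype.type(archive["run_var2"])
        model._params = params
        model.classes_ = np.asarray(archive["classes"])
        model.conv_filters_ = np.asarray(params["W"], dtype=float)
        model.sigma_ = float(np.exp(params["rho"]))
        model.readout_weights_ = np.asarray(params["V"], dtype=float)
        model.intercept_ = np.asarray(params["c"], dtype=float)
        model.n_features_in_ = nc
        model.n_parameters_ = count_parameters(
            nc, model.n_filters, model.kernel_length, 2, model.batch_norm
        )
    return model
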