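"""Readers and writers: duration files, model JSON, sweep CSVs, run manifests.

Durations travel as plain text (one value per line) or CSV with a
``duration`` column; fitted models as small JSON records; sweep landscapes as
long-format CSV.  No binary formats.
"""
from __future__ import annotations

import dataclasses
import datetime
import json
import os
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .models import BoutSample, ExponentialMixtureModel, PowerLawModel
from .model_fitting import ExpFitResult

__all__ = [
    "read_durations",
    "write_durations",
    "write_model_json",
    "read_model_json",
    "write_sweep_csv",
    "RunManifest",
]

SEED_SCHEME = (
    "master integer seed; sweep cell i runs under "
    "SeedSequence([seed, i]).generate_state(1)[0] % 2**31; iteration j of a "
    "run uses SeedSequence([cell_seed, j, 0]) for the sample and "
    "SeedSequence([cell_seed, j, 1]) for the bootstrap"
)


def read_durations(path: Union[str, os.PathLike]) -> BoutSample:
    """Read a bout-duration sample from plain text or CSV.

    Plain text holds one positive real per line; CSV needs a ``duration``
    column.  Values below one epoch are rejected: the analysis convention is
    that durations shorter than one 30-s epoch are discarded at generation
    time, so their presence indicates unprepared data.
    """
    path = os.fspath(path)
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if "," in first or first.strip().lower() == "duration":
            frame = pd.read_csv(fh)
            if "duration" not in frame.columns:
                raise ValueError(f"{path}: CSV input needs a 'duration' column")
            values = frame["duration"].to_numpy(dtype=float)
            bad = np.flatnonzero(~np.isfinite(values))
            if bad.size:
                raise ValueError(f"{path}: non-finite duration at data row {bad[0] + 1}")
        else:
            values = []
            for lineno, line in enumerate(fh, start=1):
                text = line.strip()
                if not text:
                    continue
                try:
                    values.append(float(text))
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: cannot parse {text!r} as a duration"
                    ) from None
            values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError(f"{path}: no durations found")
    if np.any(values < 1.0):
        idx = int(np.flatnonzero(values < 1.0)[0])
        raise ValueError(
            f"{path}: duration {values[idx]} < 1 epoch at entry {idx + 1}; "
            "bouts shorter than one 30-s epoch are discarded by convention "
            "and must be removed before fitting"
        )
    return BoutSample(values, {"family": "file", "path": path})


def write_durations(sample: BoutSample, path: Union[str, os.PathLike]) -> None:
    """Write one duration per line at full float precision (round-trips exactly)."""
    with open(path, "w") as fh:
        for v in sample.durations:
            fh.write(f"{float(v)!r}\n")


def write_model_json(
    model: Union[PowerLawModel, ExponentialMixtureModel, ExpFitResult],
    path: Union[str, os.PathLike],
    seed: Optional[int] = None,
) -> None:
    """Serialise a fitted model (or NLS fit outcome) to a stable JSON record."""
    if isinstance(model, ExpFitResult):
        record = {
            "family": "expmix",
            "params": None if model.model is None else {
                "amplitudes": list(model.model.amplitudes),
                "taus": list(model.model.taus),
                "offset": 0.0,
            },
            "converged": model.status == "converged",
            "constraint_ok": model.status != "constraint-violation",
            "status": model.status,
            "k": model.k,
            "seed": seed,
        }
    elif isinstance(model, ExponentialMixtureModel):
        record = {
            "family": "expmix",
            "params": {"amplitudes": list(model.amplitudes),
                       "taus": list(model.taus), "offset": 0.0},
            "converged": True, "constraint_ok": True, "k": model.k, "seed": seed,
        }
    elif isinstance(model, PowerLawModel):
        record = {
            "family": "powerlaw",
            "params": {"alpha": model.alpha, "x_min": model.x_min},
            "converged": True, "constraint_ok": True, "seed": seed,
        }
    else:
        raise TypeError(f"cannot serialise {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)
        fh.write("\n")


def read_model_json(path: Union[str, os.PathLike]):
    """Inverse of :func:`write_model_json` (returns a model instance)."""
    with open(path) as fh:
        record = json.load(fh)
    if record["family"] == "powerlaw":
        return PowerLawModel(**record["params"])
    if record["family"] == "expmix":
        if record["params"] is None:
            raise ValueError(f"{path}: record holds a non-converged fit, no model")
        p = record["params"]
        return ExponentialMixtureModel(tuple(p["amplitudes"]), tuple(p["taus"]))
    raise ValueError(f"{path}: unknown model family {record['family']!r}")


def write_sweep_csv(frame: pd.DataFrame, path: Union[str, os.PathLike]) -> None:
    """Write a sweep result DataFrame as long-format CSV (stable column order)."""
    frame.to_csv(path, index=False)


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit."""

    command: str
    config: dict
    seed: int
    seed_scheme: str = SEED_SCHEME
    version: str = __version__
    timestamp: str = ""

    def write(self, path: Union[str, os.PathLike]) -> None:
        record = dataclasses.asdict(self)
        if not record["timestamp"]:
            record["timestamp"] = datetime.datetime.now(
                datetime.timezone.utc
            ).isoformat()
        with open(path, "w") as fh:
            json.dump(record, fh, indent=2, default=str)
            fh.write("\n")
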