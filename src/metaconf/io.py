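"""CSV readers/writers, bundled fixtures, and run manifests.

Trial tables use a fixed CSV dialect: comma-separated, UTF-8, mandatory
header ``trial,d,theta,x_act,x_conf,x_new,a,z_pre,z_post,correct``, '.'
decimal, floats at 12 significant digits, empty string for missing
optional values (x_new, z_pre, z_post).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .model_core import (
    BeliefParams,
    DataError,
    GenerativeParams,
    TRIAL_COLUMNS,
    simulate_trials,
    validate_trial_table,
)

__all__ = [
    "write_trial_table",
    "read_trial_table",
    "write_metrics_csv",
    "generate_fixtures",
    "RunManifest",
]

_FLOAT_COLS = ("theta", "x_act", "x_conf", "x_new", "z_pre", "z_post")
_INT_COLS = ("trial", "d", "a")


def write_trial_table(table: pd.DataFrame, path) -> Path:
    """Write a trial table in the canonical dialect; returns the path."""
    validate_trial_table(table)
    out = table[TRIAL_COLUMNS].copy()
    out["correct"] = out["correct"].astype(bool)
    path = Path(path)
    out.to_csv(path, index=False, float_format="%.12g", na_rep="")
    return path


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial table written by :func:`write_trial_table`.

    Raises :class:`~metaconf.model_core.DataError` on a header mismatch or
    any invariant violation (action/sample inconsistency, confidence
    outside [0, 1]); the offending columns or row numbers are named.
    """
    raw = pd.read_csv(path, dtype={c: float for c in _FLOAT_COLS})
    missing = [c for c in TRIAL_COLUMNS if c not in raw.columns]
    extra = [c for c in raw.columns if c not in TRIAL_COLUMNS]
    if missing or extra:
        raise DataError(
            f"trial-table header mismatch: missing {missing}, extra {extra}"
        )
    if len(raw):
        for c in _INT_COLS:
            raw[c] = raw[c].astype(int)
        raw["correct"] = raw["correct"].astype(bool)
    validate_trial_table(raw)
    return raw


def write_metrics_csv(metrics: list[tuple], path) -> Path:
    """Write rows of (metric, value, stderr, n) as a flat CSV."""
    df = pd.DataFrame(metrics, columns=["metric", "value", "stderr", "n"])
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.12g", na_rep="")
    return path


#: Canonical parameter sets for the bundled test fixtures.
FIXTURE_SPECS = {
    "first_order": (GenerativeParams(1.0, 1.0, 1.0, 1.0), "first_order"),
    "postdecisional": (GenerativeParams(1.0, 1.0, 1.0, 1.0), "postdecisional"),
    "second_order": (GenerativeParams(1.0, 1.0, 0.6, 1.0), "second_order"),
}


def generate_fixtures(seed: int, outdir, n: int = 2000) -> dict[str, Path]:
    """Deterministic small trial tables for each model at canonical params.

    Writes ``fixture_<model>.csv`` files of ``n`` trials each and returns
    a name -> path mapping.  Regeneration with the same seed is
    byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for k, (name, (params, model_id)) in enumerate(FIXTURE_SPECS.items()):
        belief = BeliefParams.from_generative(params, model_id)
        table = simulate_trials(params, params.theta, n, belief, seed + k)
        paths[name] = write_trial_table(table, outdir / f"fixture_{name}.csv")
    return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for a run: parameters, seeds, output digests."""

    experiment_id: str
    parameters: dict
    root_seed: int
    child_seeds: dict = field(default_factory=dict)
    tool_version: str = __version__
    timestamp: str = ""
    outputs: dict = field(default_factory=dict)

    def record(self, path) -> None:
        path = Path(path)
        self.outputs[path.name] = _sha256(path)

    def write(self, path) -> Path:
        self.timestamp = self.timestamp or time.strftime(
            "%Y-%m-%dT%H:%M:%S", time.gmtime())
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")
        return path

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
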