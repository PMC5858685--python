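"""Session configuration and result serialization.

Defaults mirror the standard 6-octave-band setup: centers 250 Hz-8 kHz,
TMRs -5..15 dB in 5-dB steps, 2-5 presented bands, a 300-trial budget.
Everything a command does is a deterministic function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .sii_core import BandGrid, DEFAULT_CENTERS_HZ

__all__ = ["SessionConfig", "load_config", "save_config", "write_results", "read_trial_log"]


@dataclass(frozen=True)
class SessionConfig:
    center_frequencies_hz: tuple[float, ...] = DEFAULT_CENTERS_HZ
    tmr_grid_db: tuple[float, ...] = (-5.0, 0.0, 5.0, 10.0, 15.0)
    presented_range: tuple[int, int] = (2, 5)
    trial_budget: int = 300
    ridge: float = 0.01
    optimizer_mode: str = "refit"  # "refit" | "fisher"
    #: regression link; only "logistic" is implemented ("asymmetric" is a
    #: reserved hook and rejected at validation)
    link: str = "logistic"
    seed: int = 0
    strategy: str = "qbif"  # "qbif" | "compound" | "random"
    #: simulated-listener spec ({"weights": [...], "Q": .., "N": .., "P": ..})
    #: or None for an externally supplied response callback
    listener: dict | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "center_frequencies_hz", tuple(float(c) for c in self.center_frequencies_hz)
        )
        object.__setattr__(self, "tmr_grid_db", tuple(float(t) for t in self.tmr_grid_db))
        object.__setattr__(
            self, "presented_range", tuple(int(v) for v in self.presented_range)
        )
        self.validate()

    def validate(self) -> None:
        n = len(self.center_frequencies_hz)
        if n < 2:
            raise ConfigError("center_frequencies_hz: need at least 2 bands")
        lo, hi = self.presented_range
        if not (1 <= lo <= hi <= n):
            raise ConfigError(
                f"presented_range: ({lo}, {hi}) must lie within [1, {n}]"
            )
        if len(self.tmr_grid_db) == 0:
            raise ConfigError("tmr_grid_db: must be non-empty")
        if self.trial_budget < 1:
            raise ConfigError("trial_budget: must be >= 1")
        if self.ridge < 0:
            raise ConfigError("ridge: must be >= 0")
        if self.optimizer_mode not in ("refit", "fisher"):
            raise ConfigError(f"optimizer_mode: unknown mode {self.optimizer_mode!r}")
        if self.link != "logistic":
            raise ConfigError(
                f"link: only 'logistic' is implemented (got {self.link!r})"
            )
        if self.strategy not in ("qbif", "compound", "random"):
            raise ConfigError(f"strategy: unknown strategy {self.strategy!r}")

    def band_grid(self) -> BandGrid:
        return BandGrid(self.center_frequencies_hz)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["center_frequencies_hz"] = list(self.center_frequencies_hz)
        d["tmr_grid_db"] = list(self.tmr_grid_db)
        d["presented_range"] = list(self.presented_range)
        return d


def load_config(path) -> SessionConfig:
    """Load a YAML (or JSON) config; missing keys take the defaults, an
    empty file yields the all-default config."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not parseable YAML: {exc}")
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {f.name for f in dataclasses.fields(SessionConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown field(s) {sorted(unknown)}")
    try:
        return SessionConfig(**raw)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"{path}: {exc}")


def save_config(config: SessionConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_results(session, out_dir) -> dict:
    """Serialize a session: trial log (JSON-lines), final-estimate JSON,
    per-trial metrics CSV, and a manifest with content hashes."""
    from . import __version__

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}")

    log_path = out / "trials.jsonl"
    with log_path.open("w") as fh:
        for k, (rec, phase) in enumerate(zip(session.records, session.phases)):
            row = {
                "trial": k + 1,
                "phase": phase,
                "tmr_db": rec.stimulus.tmr_db,
                "mask": rec.stimulus.mask_string(),
                "in_quiet": rec.stimulus.in_quiet,
                "correct": bool(rec.correct),
                "coef": [round(v, 12) for v in session.interim_coef[k]],
                "logdet_cov": round(float(session.interim_logdet[k]), 12),
            }
            fh.write(json.dumps(row) + "\n")

    est_path = out / "estimates.json"
    est = {
        "version": __version__,
        "seed": session.seed,
        "config": session.config.to_dict(),
        "n_trials": session.n_trials,
        "n_training": session.n_training,
        "proportion_correct": session.proportion_correct if session.records else None,
        "weights": list(session.weights.values) if session.weights else None,
        "srt_db": session.link.srt_db if session.link else None,
        "beta": session.link.beta if session.link else None,
        "coef_mean": list(session.posterior.coef_mean) if session.posterior else None,
        "coef_cov": [list(r) for r in session.posterior.coef_cov]
        if session.posterior
        else None,
    }
    est_path.write_text(json.dumps(est, indent=2) + "\n")

    metrics_path = out / "metrics.csv"
    with metrics_path.open("w") as fh:
        fh.write("trial,phase,correct,logdet_cov\n")
        for k, (rec, phase) in enumerate(zip(session.records, session.phases)):
            fh.write(
                f"{k + 1},{phase},{int(rec.correct)},{session.interim_logdet[k]:.10g}\n"
            )

    files = [log_path, est_path, metrics_path]
    manifest = {
        "n_trials": session.n_trials,
        "files": [{"name": p.name, "sha256": _sha256(p)} for p in files],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def read_trial_log(path):
    """Read a trials.jsonl log back into TrialRecord objects."""
    from .inference import TrialRecord
    from .sii_core import StimulusSpec

    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        row = json.loads(line)
        stim = StimulusSpec(
            tmr_db=float(row["tmr_db"]),
            band_mask=tuple(ch == "1" for ch in row["mask"]),
            in_quiet=bool(row.get("in_quiet", False)),
        )
        records.append(TrialRecord(stimulus=stim, correct=bool(row["correct"])))
    return records
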