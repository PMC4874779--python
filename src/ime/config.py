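"""Run configuration: one structured-text (YAML) document drives a run.

Every source of randomness must carry an explicit seed; unknown keys are
rejected so that typos fail loudly.
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .simulate import MismatchSpec, SessionSpec

__all__ = ["RunConfig", "run_config", "default_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


_SESSION_KEYS = set(SessionSpec.__dataclass_fields__)
_MISMATCH_KEYS = set(MismatchSpec.__dataclass_fields__)
_TOP_KEYS = {"session", "mismatch", "seed", "ground_truth", "fit"}
_GT_KEYS = {"null_sigma", "aim_mode", "mapping_seed"}
_FIT_KEYS = {"tau", "max_iter", "tol", "folds", "variant", "seed"}


class RunConfig:
    """Validated configuration for simulate/fit/analyze runs."""

    def __init__(self, session: SessionSpec, mismatch: MismatchSpec, seed: int,
                 ground_truth: dict, fit: dict):
        self.session = session
        self.mismatch = mismatch
        self.seed = seed
        self.ground_truth = ground_truth
        self.fit = fit

    def to_dict(self) -> dict:
        return {
            "session": {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in asdict(self.session).items()},
            "mismatch": asdict(self.mismatch),
            "seed": self.seed,
            "ground_truth": dict(self.ground_truth),
            "fit": dict(self.fit),
        }

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def parse_config(doc: dict) -> RunConfig:
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping")
    _check_keys(doc, _TOP_KEYS, "config")
    if "seed" not in doc:
        raise ConfigError("config requires an explicit top-level seed")
    sess = dict(doc.get("session", {}))
    _check_keys(sess, _SESSION_KEYS, "session")
    if "hold_steps" in sess:
        sess["hold_steps"] = tuple(sess["hold_steps"])
    mm = dict(doc.get("mismatch", {}))
    _check_keys(mm, _MISMATCH_KEYS, "mismatch")
    gt = dict(doc.get("ground_truth", {}))
    _check_keys(gt, _GT_KEYS, "ground_truth")
    fit = dict(doc.get("fit", {}))
    _check_keys(fit, _FIT_KEYS, "fit")
    return RunConfig(
        session=SessionSpec(**sess),
        mismatch=MismatchSpec(**mm),
        seed=int(doc["seed"]),
        ground_truth=gt,
        fit=fit,
    )


def run_config(path) -> RunConfig:
    """Load and validate a run configuration file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parse_config(doc)


def default_config(seed: int = 0) -> RunConfig:
    return parse_config({"seed": seed})
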