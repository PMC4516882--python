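"""Parameter/configuration I/O and run manifests.

Parameter files are YAML with a versioned schema and unit-suffixed keys
(``cl_L_per_h_per_70kg`` rather than a bare ``cl``) so a file can never
be silently interpreted in the wrong units. Two parameter sets ship with
the package: the final-model and bootstrap-average columns of the
published estimates.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import yaml

from .kpd_core import StructuralParams
from .population import VarianceComponents

__all__ = [
    "PARAM_SCHEMA",
    "load_params",
    "save_params",
    "default_params",
    "save_fit",
    "load_fit_params",
    "RunManifest",
    "write_manifest",
]

PARAM_SCHEMA = "snpkpd-params/1"

_THETA_KEYS = {
    "cl_L_per_h_per_70kg": "cl_std",
    "v_L_per_70kg": "v_std",
    "s0_mmHg": "s0_std",
    "pwr_age": "pwr_age",
    "median_age_y": "median_age",
    "emax_mmHg": "emax",
    "ec50_low_ug_per_L": "ec50_low",
    "ec50_high_ug_per_L": "ec50_high",
    "gamma": "gamma",
    "slope_mmHg_per_h": "slope",
    "p_high": "p_high",
}
_OMEGA_KEYS = {
    "v": "omega_v",
    "cl": "omega_cl",
    "s0": "omega_s0",
    "ec50_low": "omega_ec50_low",
    "ec50_high": "omega_ec50_high",
    "emax": "omega_emax",
    "slope": "omega_slope",
}


class ParamFileError(ValueError):
    """Invalid parameter file; the message names the offending field."""


def _parse_params(doc: dict, source: str) -> tuple[StructuralParams, VarianceComponents]:
    if not isinstance(doc, dict):
        raise ParamFileError(f"{source}: expected a mapping at the top level")
    if doc.get("schema") != PARAM_SCHEMA:
        raise ParamFileError(f"{source}: missing or unsupported schema (expected {PARAM_SCHEMA!r})")
    extra = set(doc) - {"schema", "theta", "omega", "sigma"}
    if extra:
        raise ParamFileError(f"{source}: unknown top-level keys {sorted(extra)}")

    theta_doc = doc.get("theta", {})
    unknown = set(theta_doc) - set(_THETA_KEYS)
    if unknown:
        raise ParamFileError(f"{source}: unknown theta keys {sorted(unknown)}")
    missing = set(_THETA_KEYS) - set(theta_doc)
    if missing:
        raise ParamFileError(f"{source}: missing theta keys {sorted(missing)}")
    try:
        theta = StructuralParams(**{field: float(theta_doc[key]) for key, field in _THETA_KEYS.items()})
    except ValueError as exc:
        raise ParamFileError(f"{source}: {exc}") from exc

    omega_doc = doc.get("omega", {})
    unknown = set(omega_doc) - set(_OMEGA_KEYS)
    if unknown:
        raise ParamFileError(f"{source}: unknown omega keys {sorted(unknown)}")
    sigma_doc = doc.get("sigma", {})
    unknown = set(sigma_doc) - {"prop"}
    if unknown:
        raise ParamFileError(f"{source}: unknown sigma keys {sorted(unknown)}")
    try:
        omega = VarianceComponents(
            **{field: float(omega_doc.get(key, 0.0)) for key, field in _OMEGA_KEYS.items()},
            sigma_prop=float(sigma_doc.get("prop", 0.0)),
        )
    except ValueError as exc:
        raise ParamFileError(f"{source}: {exc}") from exc
    return theta, omega


def load_params(path: str | Path) -> tuple[StructuralParams, VarianceComponents]:
    """Load and validate a parameter YAML file."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    return _parse_params(doc, str(path))


def save_params(theta: StructuralParams, omega: VarianceComponents, path: str | Path) -> None:
    doc = {
        "schema": PARAM_SCHEMA,
        "theta": {key: getattr(theta, field) for key, field in _THETA_KEYS.items()},
        "omega": {key: getattr(omega, field) for key, field in _OMEGA_KEYS.items()},
        "sigma": {"prop": omega.sigma_prop},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def default_params(column: str = "model") -> tuple[StructuralParams, VarianceComponents]:
    """Packaged published estimates: ``column`` is 'model' or 'bootstrap'."""
    if column not in ("model", "bootstrap"):
        raise ValueError("column must be 'model' or 'bootstrap'")
    ref = resources.files("snpkpd.data").joinpath(f"table2_{column}.yaml")
    doc = yaml.safe_load(ref.read_text())
    return _parse_params(doc, f"packaged table2_{column}.yaml")


def save_fit(fit, path: str | Path) -> None:
    """Write a fit result as JSON (estimates, variability, OFV, bookkeeping)."""
    theta, omega = fit.theta_hat, fit.omega_hat
    doc = {
        "schema": "snpkpd-fit/1",
        "ofv": fit.ofv,
        "converged": fit.converged,
        "n_subjects": fit.n_subjects,
        "n_obs": fit.n_obs,
        "n_iter": fit.n_iter,
        "message": fit.message,
        "fixed": sorted(fit.fixed),
        "theta": {key: getattr(theta, field) for key, field in _THETA_KEYS.items()},
        "omega": {key: getattr(omega, field) for key, field in _OMEGA_KEYS.items()},
        "sigma": {"prop": omega.sigma_prop},
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_fit_params(path: str | Path) -> tuple[StructuralParams, VarianceComponents]:
    """Read the parameter estimates back out of a fit JSON."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != "snpkpd-fit/1":
        raise ParamFileError(f"{path}: not a fit file")
    return _parse_params(
        {"schema": PARAM_SCHEMA, "theta": doc["theta"], "omega": doc["omega"], "sigma": doc["sigma"]},
        str(path),
    )


@dataclass
class RunManifest:
    """Provenance of one CLI invocation: enough to replay it exactly."""

    command: str
    arguments: dict
    seed: int | None
    config_hashes: dict
    package_version: str
    inputs: list[str]
    outputs: list[str]
    started_utc: str
    finished_utc: str
    host: str


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    out_path: str | Path,
    command: str,
    arguments: dict,
    seed: int | None,
    inputs: list[str | Path],
    outputs: list[str | Path],
    started: datetime,
) -> Path:
    from . import __version__

    manifest = RunManifest(
        command=command,
        arguments={k: (str(v) if isinstance(v, Path) else v) for k, v in arguments.items()},
        seed=seed,
        config_hashes={str(p): _sha256(p) for p in inputs if Path(p).exists()},
        package_version=__version__,
        inputs=[str(p) for p in inputs],
        outputs=[str(p) for p in outputs],
        started_utc=started.astimezone(timezone.utc).isoformat(),
        finished_utc=datetime.now(timezone.utc).isoformat(),
        host=platform.node(),
    )
    path = Path(str(out_path) + ".manifest.json")
    path.write_text(json.dumps(asdict(manifest), indent=2) + "\n")
    return path
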