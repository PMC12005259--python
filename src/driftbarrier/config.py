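"""Configuration files, presets, and run artifacts.

Scenarios can be described in TOML (``[model]`` / ``[schedule]`` /
``[site_types]`` sections) or JSON with the same structure.  Unknown keys are
rejected rather than ignored, so a typo cannot silently fall back to a
default.  The preset catalog encodes the simulation study's parameter grids
at two scales: ``"paper"`` (full burn-in of 1000 N generations, assays every
N/10 generations -- cluster wall-time) and ``"desk"`` (N rescaled down to
1000 holding N u10, N u01 and N s fixed, shorter burn-in backed by a
stationarity diagnostic).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .engine import Trajectory, mutation_rate_for_N, rescale_config
from .model import ModelConfig, SiteTypeScheme

__all__ = [
    "load_config",
    "write_config",
    "scenario",
    "PRESETS",
    "build_preset",
    "RunManifest",
    "write_trajectory",
]

_MODEL_KEYS = {
    "N", "L", "s", "theta_S", "u10", "beta",
    "track_neutral", "neutral_mu", "init_state",
}
_SCHEDULE_KEYS = {
    "burn_in_generations", "sample_interval_generations", "n_samples",
}


def _reject_unknown(section: str, given: dict, allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise KeyError(
            f"unknown key(s) {sorted(unknown)} in [{section}]; "
            f"allowed: {sorted(allowed)}"
        )


def load_config(path: str | Path) -> tuple[ModelConfig, SiteTypeScheme | None]:
    """Load and validate a scenario file (.toml or .json).

    Returns the model configuration and, if a ``[site_types]`` section is
    present, the multi-type scheme.  Missing required keys, invariant
    violations and unknown keys each raise with a distinct message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".json":
        raw = json.loads(path.read_text())
    elif path.suffix == ".toml":
        raw = tomllib.loads(path.read_text())
    else:
        raise ValueError(f"unsupported config format {path.suffix!r} (use .toml/.json)")

    _reject_unknown("top level", raw, {"model", "schedule", "site_types", "seed"})
    model = dict(raw.get("model", {}))
    _reject_unknown("model", model, _MODEL_KEYS)
    missing = {"N", "L", "s", "theta_S", "u10", "beta"} - set(model)
    if missing:
        raise KeyError(f"missing required model key(s): {sorted(missing)}")
    schedule = dict(raw.get("schedule", {}))
    _reject_unknown("schedule", schedule, _SCHEDULE_KEYS)

    config = ModelConfig(seed=int(raw.get("seed", 0)), **model, **schedule)

    scheme = None
    if "site_types" in raw:
        st = dict(raw["site_types"])
        _reject_unknown("site_types", st, {"classes", "theta_P"})
        if "classes" not in st:
            raise KeyError("missing required site_types key: 'classes'")
        classes = tuple((int(Lx), float(sx)) for Lx, sx in st["classes"])
        scheme = SiteTypeScheme(
            classes=classes, theta_P=float(st.get("theta_P", float("nan")))
        )
    return config, scheme


def _config_dict(config: ModelConfig) -> dict:
    d = dataclasses.asdict(config)
    return {
        "seed": d.pop("seed"),
        "model": {k: d[k] for k in _MODEL_KEYS if d[k] is not None},
        "schedule": {k: d[k] for k in _SCHEDULE_KEYS if d[k] is not None},
    }


def write_config(
    config: ModelConfig, path: str | Path, scheme: SiteTypeScheme | None = None
) -> None:
    """Serialize a scenario to TOML or JSON (round-trips through
    :func:`load_config`)."""
    path = Path(path)
    doc = _config_dict(config)
    if scheme is not None:
        doc["site_types"] = {
            "classes": [list(c) for c in scheme.classes],
            "theta_P": scheme.theta_P,
        }
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
        return
    if path.suffix != ".toml":
        raise ValueError(f"unsupported config format {path.suffix!r}")
    lines = [f"seed = {doc['seed']}"]
    for section in ("model", "schedule", "site_types"):
        if section not in doc or not doc[section]:
            continue
        lines.append(f"\n[{section}]")
        for k, v in doc[section].items():
            if isinstance(v, bool):
                lines.append(f"{k} = {'true' if v else 'false'}")
            elif isinstance(v, list):
                lines.append(f"{k} = {json.dumps(v)}")
            else:
                lines.append(f"{k} = {v!r}" if isinstance(v, str) else f"{k} = {v}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# preset catalog


def scenario(
    L: int,
    Ns: float,
    beta: float = 1.0,
    x: float = 0.5,
    scale: str = "desk",
    N: int = 10_000,
    seed: int = 0,
    track_neutral: bool = False,
    s_zero: bool = False,
    n_samples: int | None = None,
) -> ModelConfig:
    """Build one study cell: ``N s = Ns``, optimum at ``theta_S = x L``,
    mutation rate from the empirical N-scaling.

    ``scale="paper"`` keeps the census size with the full burn-in (1000 N)
    and N/10 assay interval; ``scale="desk"`` rescales to N' = 1000
    (preserving N u10, N u01 and N s), burns in for 100 N' generations, and
    samples every 10 generations (denser than N/10 so that >= 1e5 samples
    stay within desk wall-time; time averages are unbiased under the
    autocorrelation this induces).  ``s_zero`` builds the matched neutral
    control of a cell.
    """
    s = 0.0 if s_zero else Ns / N
    config = ModelConfig(
        N=N,
        L=L,
        s=s,
        theta_S=x * L,
        u10=mutation_rate_for_N(N),
        beta=beta,
        seed=seed,
        track_neutral=track_neutral,
        n_samples=n_samples
        if n_samples is not None
        else (1_000_000 if scale == "paper" else 100_000),
    )
    if scale == "paper":
        return config
    if scale != "desk":
        raise ValueError(f"unknown scale {scale!r}")
    config = rescale_config(config)
    return config.with_(
        burn_in_generations=100 * config.N,
        sample_interval_generations=10,
    )


#: named presets: name -> (description, kwargs for :func:`scenario`)
PRESETS: dict[str, tuple[str, dict]] = {
    **{
        f"intermediate-L{L}-Ns{Ns}": (
            f"no-bias intermediate optimum, L={L}, Ns={Ns}",
            {"L": L, "Ns": Ns, "beta": 1.0, "x": 0.5},
        )
        for L in (10, 100, 1000, 10_000)
        for Ns in (1, 10)
    },
    **{
        f"halfgauss-L{L}-beta{beta}-Ns{Ns}": (
            f"half-Gaussian optimum (theta_S=L), L={L}, beta={beta}, Ns={Ns}",
            {"L": L, "Ns": Ns, "beta": beta, "x": 1.0},
        )
        for L in (100, 1000)
        for beta in (1.0, 0.33)
        for Ns in (1, 10)
    },
    "interference-L1000-beta0.33-Ns10": (
        "large-block interference cell (intermediate optimum, biased mutation)",
        {"L": 1000, "Ns": 10, "beta": 0.33, "x": 0.5},
    ),
    "neutral-marker-selected": (
        "intermediate optimum L=100, Ns=10 with embedded neutral marker",
        {"L": 100, "Ns": 10, "beta": 1.0, "x": 0.5, "track_neutral": True},
    ),
    "neutral-marker-control": (
        "matched s=0 control with embedded neutral marker",
        {"L": 100, "Ns": 10, "beta": 1.0, "x": 0.5, "track_neutral": True,
         "s_zero": True},
    ),
}


def build_preset(name: str, scale: str = "desk", seed: int = 0) -> ModelConfig:
    """Instantiate a named preset at the requested scale."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; see PRESETS for the catalog")
    _, kwargs = PRESETS[name]
    return scenario(scale=scale, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# run artifacts


@dataclass(frozen=True)
class RunManifest:
    """Sidecar metadata sufficient to reproduce a run exactly."""

    config: dict
    seed: int
    version: str
    generator: str
    start_generation: int
    end_generation: int
    outputs: dict  # path -> sha256

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    def verify(self) -> bool:
        """Check that every listed output exists and matches its checksum."""
        return all(
            Path(p).exists() and _sha256(p) == digest
            for p, digest in self.outputs.items()
        )


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_trajectory(
    traj: Trajectory,
    config: ModelConfig,
    out_dir: str | Path,
    stem: str = "trajectory",
) -> RunManifest:
    """Write a trajectory TSV plus its JSON manifest; returns the manifest.

    Tab-separated, one header row, '.' decimal, floats at 10 significant
    digits; untracked columns are left empty.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / f"{stem}.tsv"
    frame = traj.to_frame()
    frame.to_csv(tsv, sep="\t", index=False, float_format="%.10g", na_rep="")
    manifest = RunManifest(
        config=_config_dict(config),
        seed=config.seed,
        version=__version__,
        generator="numpy.random.Generator(PCG64)",
        start_generation=int(traj.generation[0]) if len(traj) else 0,
        end_generation=int(traj.generation[-1]) if len(traj) else 0,
        outputs={str(tsv): _sha256(tsv)},
    )
    manifest.write(out_dir / f"{stem}.manifest.json")
    return manifest
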