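"""Config-driven pipeline: simulate -> render -> segment -> summarise.

A run is described by a small YAML/JSON mapping (see :data:`CONFIG_SCHEMA`):
a chi_AB sweep is simulated, final snapshots rendered to two-channel TIFFs,
segmented, and per-condensate plus per-chi summary CSVs written, together with
a provenance sidecar (config hash, package version, seed).  All outputs are
deterministic functions of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, fh, morphometry
from .errors import ConfigError
from .image import write_tiff

log = logging.getLogger("nsphase")

#: Recognised configuration keys -> (type, default).  ``None`` default means required.
CONFIG_SCHEMA: dict[str, tuple[type, object]] = {
    "chi_ab_values": (list, None),
    "chi_aa": (float, 4.0),
    "chi_bb": (float, 4.0),
    "phi_a": (float, 0.23),
    "phi_b": (float, 0.23),
    "grid_n": (int, 128),
    "dt": (float, 0.1),
    "total_steps": (int, fh.DEFAULT_TOTAL_STEPS),
    "seed": (int, 0),
    "out_dir": (str, "nsphase_out"),
    "write_tiffs": (bool, True),
    "min_area": (int, 64),
}


@dataclass
class RunConfig:
    chi_ab_values: list[float]
    chi_aa: float = 4.0
    chi_bb: float = 4.0
    phi_a: float = 0.23
    phi_b: float = 0.23
    grid_n: int = 128
    dt: float = 0.1
    total_steps: int = fh.DEFAULT_TOTAL_STEPS
    seed: int = 0
    out_dir: str = "nsphase_out"
    write_tiffs: bool = True
    min_area: int = 64
    raw: dict = field(default_factory=dict, repr=False)


def validate_config(data: dict) -> RunConfig:
    """Schema-validate a config mapping; raise :class:`ConfigError` on violation."""
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(data) - set(CONFIG_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    for key, (typ, default) in CONFIG_SCHEMA.items():
        if key in data:
            val = data[key]
            if typ is float and isinstance(val, int):
                val = float(val)
            if typ is int and isinstance(val, bool):
                raise ConfigError(f"{key}: expected {typ.__name__}")
            if not isinstance(val, typ):
                raise ConfigError(f"{key}: expected {typ.__name__}, got {type(val).__name__}")
        elif default is None:
            raise ConfigError(f"missing required key: {key}")
        else:
            val = default
        kwargs[key] = val
    vals = kwargs["chi_ab_values"]
    if not vals or not all(isinstance(v, (int, float)) for v in vals):
        raise ConfigError("chi_ab_values must be a non-empty list of numbers")
    kwargs["chi_ab_values"] = [float(v) for v in vals]
    return RunConfig(**kwargs, raw=dict(data))


def load_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config: {exc}") from exc
    return validate_config(data)


def _provenance(cfg: RunConfig) -> dict:
    canonical = json.dumps(cfg.raw or asdict_no_raw(cfg), sort_keys=True)
    return {
        "package": "nsphase",
        "version": __version__,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": cfg.seed,
    }


def asdict_no_raw(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d.pop("raw", None)
    return d


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the sweep pipeline and write all artifacts under ``cfg.out_dir``.

    Returns a dict with the output paths and the summary DataFrame.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = fh.FHParams(
        chi_AA=cfg.chi_aa, chi_BB=cfg.chi_bb, phi_A0=cfg.phi_a, phi_B0=cfg.phi_b,
        grid_n=cfg.grid_n, dt=cfg.dt, seed=cfg.seed,
    )
    mcfg = morphometry.MorphometryConfig(min_area=cfg.min_area)
    snapshot_steps = fh.default_snapshot_steps(cfg.total_steps)
    log.info("sweep over chi_AB=%s (grid %d^2, %d steps)",
             cfg.chi_ab_values, cfg.grid_n, cfg.total_steps)

    per_cond = []
    rows = []
    for i, chi in enumerate(cfg.chi_ab_values):
        from dataclasses import replace
        p = replace(params, chi_AB=float(chi), seed=cfg.seed + i)
        final = fh.run(p, snapshot_steps)[-1]
        img = fh.render_snapshot(final)
        if cfg.write_tiffs:
            write_tiff(out / f"snapshot_chi_{chi:g}.tif", img)
        df = morphometry.records_to_dataframe(
            morphometry.analyze_image_periodic(img, mcfg), chi
        )
        per_cond.append(df)
        biph = df[df["n_domains"] >= 2]
        ma, mb = fh.mass_error(final, p)
        rows.append({
            "chi_AB": float(chi),
            "n_condensates": len(df),
            "n_biphasic": len(biph),
            "cos_half_theta_median": biph["cos_half_theta"].median() if len(biph) else float("nan"),
            "rho_A_median": df["rho_A"].median() if len(df) else float("nan"),
            "rho_B_median": df["rho_B"].median() if len(df) else float("nan"),
            "mass_error_A": ma,
            "mass_error_B": mb,
            "free_energy": fh.total_free_energy(final, p),
        })
    summary = pd.DataFrame(rows)
    cond_df = pd.concat(per_cond, ignore_index=True) if per_cond else pd.DataFrame()
    cond_path = out / "condensates.csv"
    summary_path = out / "summary.csv"
    cond_df.to_csv(cond_path, index=False)
    summary.to_csv(summary_path, index=False)
    sidecar = _provenance(cfg)
    sidecar["config"] = asdict_no_raw(cfg)
    (out / "provenance.json").write_text(json.dumps(sidecar, indent=2))
    log.info("wrote %s and %s", cond_path, summary_path)
    return {"summary": summary, "condensates": cond_df,
            "summary_path": summary_path, "condensates_path": cond_path}
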