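"""Programmatic parameter sweeps and canned initial shapes for tests and demos.

Every emitted parameter set satisfies the positive-equilibrium condition
mu_f/r + mu_m/(1-r) < sigma/4, filtered by construction.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .io import save_config
from .local_dynamics import stability_condition_two_sex
from .params import ModelParams

__all__ = ["default_parameter_sweep", "generate_fixtures", "CANONICAL"]

#: canonical symmetric parameter set used across examples and tests
CANONICAL = ModelParams(r=0.5, mu_f=0.05, mu_m=0.05, D_f=1.0, D_m=1.0, sigma=1.0)


def default_parameter_sweep(
    mu_values=(0.02, 0.035, 0.05),
    r_values=(0.35, 0.5, 0.65),
    D_values=(0.25, 1.0, 4.0),
    sigma: float = 1.0,
) -> list[ModelParams]:
    """Cartesian sweep over mortalities, sex ratios and diffusivities,
    keeping only parameter sets with a positive stable equilibrium."""
    out = []
    for mu in mu_values:
        for r in r_values:
            for D in D_values:
                p = ModelParams(r=r, mu_f=mu, mu_m=mu, D_f=D, D_m=D, sigma=sigma)
                if stability_condition_two_sex(p):
                    out.append(p)
    return out


def random_admissible_params(
    rng: np.random.Generator, n: int, sigma: float = 1.0, margin: float = 0.9
) -> list[ModelParams]:
    """Random parameter sets with mortality load A strictly below margin*sigma/4."""
    out = []
    while len(out) < n:
        r = rng.uniform(0.15, 0.85)
        mu_f = rng.uniform(0.005, 0.08)
        mu_m = rng.uniform(0.005, 0.08)
        p = ModelParams(r=r, mu_f=mu_f, mu_m=mu_m, sigma=sigma)
        if p.A < margin * sigma / 4.0:
            out.append(p)
    return out


def generate_fixtures(out_dir, spec: Optional[dict] = None) -> list[Path]:
    """Write parameter sweeps and canned rectangular shapes as JSON configs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = spec or {}
    sweep = default_parameter_sweep(
        mu_values=spec.get("mu_values", (0.02, 0.035, 0.05)),
        r_values=spec.get("r_values", (0.35, 0.5, 0.65)),
        D_values=spec.get("D_values", (0.25, 1.0, 4.0)),
        sigma=spec.get("sigma", 1.0),
    )
    written = []
    path = out_dir / "parameter_sweep.json"
    save_config({"parameter_sets": [p.to_dict() for p in sweep]}, path)
    written.append(path)
    path = out_dir / "canonical.json"
    save_config({"model": CANONICAL.to_dict()}, path)
    written.append(path)
    shapes = {
        "rectangles": [
            {"n_f": 0.3, "n_m": 0.3, "L_f": 10.0, "L_m": 10.0},
            {"n_f": 0.36, "n_m": 0.36, "L_f": 6.0, "L_m": 6.0},
        ]
    }
    path = out_dir / "shapes.json"
    save_config(shapes, path)
    written.append(path)
    return written
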