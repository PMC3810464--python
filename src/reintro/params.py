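"""Parameter containers for the two-sex and reduced single-sex models.

All rates are per unit time, diffusion coefficients in squared length per
unit time, and densities are dimensionless occupancies (the carrying
capacity of fully occupied habitat is 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the two-sex reaction-diffusion model.

    Parameters
    ----------
    r:
        Sex ratio at birth: fraction of offspring born female, in (0, 1).
    mu_f, mu_m:
        Density-independent per-capitum mortality rates for females and
        males (1/time), both positive.
    D_f, D_m:
        Diffusion coefficients for females and males (length^2/time).
    sigma:
        Scale of the mass-action birth term (1/(density*time)).
        Defaults to 1, which fixes the time unit.
    """

    r: float = 0.5
    mu_f: float = 0.05
    mu_m: float = 0.05
    D_f: float = 1.0
    D_m: float = 1.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.r < 1.0:
            raise ValueError(f"sex ratio r must be in (0,1), got {self.r}")
        if self.mu_f <= 0.0 or self.mu_m <= 0.0:
            raise ValueError("mortality rates must be positive")
        if self.D_f < 0.0 or self.D_m < 0.0:
            raise ValueError("diffusion coefficients must be non-negative")
        if self.sigma <= 0.0:
            raise ValueError("sigma must be positive")

    @property
    def A(self) -> float:
        """Mortality load mu_f/r + mu_m/(1-r); positive equilibria exist iff A < sigma/4."""
        return self.mu_f / self.r + self.mu_m / (1.0 - self.r)

    @property
    def is_symmetric(self) -> bool:
        return (
            self.r == 0.5 and self.mu_f == self.mu_m and self.D_f == self.D_m
        )

    def to_single_sex(self) -> "SingleSexParams":
        """Reduce to the symmetric single-sex model (requires symmetry)."""
        if not self.is_symmetric:
            raise ValueError("single-sex reduction requires r=1/2, equal mortalities and diffusivities")
        return SingleSexParams(mu=self.mu_f, D=self.D_f, sigma=self.sigma)

    def diffusion_length(self) -> float:
        """Characteristic length sqrt(max(D)/min(mu)) used for grid sizing."""
        return math.sqrt(max(self.D_f, self.D_m, 1e-12) / min(self.mu_f, self.mu_m))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SingleSexParams:
    """Constants of the reduced (symmetric) single-sex model.

    The reduction sets r = 1/2, mu_f = mu_m = mu, D_f = D_m = D and
    identical initial distributions for the sexes, after which both
    densities follow u_t = D u_xx + (sigma/2) u^2 (1 - 2u) - mu u.
    """

    mu: float = 0.05
    D: float = 1.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.mu <= 0.0:
            raise ValueError("mu must be positive")
        if self.D < 0.0:
            raise ValueError("D must be non-negative")
        if self.sigma <= 0.0:
            raise ValueError("sigma must be positive")

    def to_two_sex(self) -> ModelParams:
        return ModelParams(
            r=0.5, mu_f=self.mu, mu_m=self.mu, D_f=self.D, D_m=self.D, sigma=self.sigma
        )

    def diffusion_length(self) -> float:
        return math.sqrt(max(self.D, 1e-12) / self.mu)

    def to_dict(self) -> dict:
        return asdict(self)
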