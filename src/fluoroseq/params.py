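"""Error-model and intensity parameters of the sequencing process.

The per-cycle chemistry is described by four error rates and three
intensity parameters, all of which may differ per fluorophore color
(channel) except the Edman failure and detachment rates, which act on the
whole peptide:

``p``        per-cycle dye destruction (photobleaching) probability, per channel
``m``        missing-fluorophore ("dud" dye) probability, per channel
``e``        Edman cycle failure probability (the cycle removes no residue)
``d``        per-cycle peptide detachment probability (absorbing)
``mu``       mean fluorescence intensity of one fluorophore, per channel
``sigma``    per-fluorophore intensity standard deviation, per channel
``sigma_bg`` background (zero-fluorophore) intensity standard deviation

A cell with ``lam`` surviving fluorophores reads out as
``Normal(lam * mu, sigma_bg**2 + lam * sigma**2)``.

Defaults follow published estimates for the dye Atto647N:
p=0.05, m=0.07, e=0.06, d=0.05, mu=1.0, sigma=0.16, sigma_bg=0.00667.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence, Union

import numpy as np

Scalarish = Union[float, Sequence[float], np.ndarray]

DEFAULT_P = 0.05
DEFAULT_M = 0.07
DEFAULT_E = 0.06
DEFAULT_D = 0.05
DEFAULT_MU = 1.0
DEFAULT_SIGMA = 0.16
DEFAULT_SIGMA_BG = 0.00667
DEFAULT_NUM_TIMESTEPS = 10


def _channel_array(value: Scalarish, n_channels: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_channels, float(arr))
    if arr.shape != (n_channels,):
        raise ValueError(f"{name} must be a scalar or length-{n_channels} sequence")
    return arr


@dataclass(frozen=True)
class SequencingParams:
    """All rates and intensity-distribution parameters, plus the number of
    imaging timesteps ``num_timesteps`` (observations per read)."""

    n_channels: int
    p: np.ndarray
    m: np.ndarray
    e: float
    d: float
    mu: np.ndarray
    sigma: np.ndarray
    sigma_bg: np.ndarray
    num_timesteps: int = DEFAULT_NUM_TIMESTEPS

    @classmethod
    def create(
        cls,
        n_channels: int,
        *,
        p: Scalarish = DEFAULT_P,
        m: Scalarish = DEFAULT_M,
        e: float = DEFAULT_E,
        d: float = DEFAULT_D,
        mu: Scalarish = DEFAULT_MU,
        sigma: Scalarish = DEFAULT_SIGMA,
        sigma_bg: Scalarish = DEFAULT_SIGMA_BG,
        num_timesteps: int = DEFAULT_NUM_TIMESTEPS,
    ) -> "SequencingParams":
        if n_channels < 1:
            raise ValueError("need at least one channel")
        if num_timesteps < 1:
            raise ValueError("need at least one timestep")
        params = cls(
            n_channels=n_channels,
            p=_channel_array(p, n_channels, "p"),
            m=_channel_array(m, n_channels, "m"),
            e=float(e),
            d=float(d),
            mu=_channel_array(mu, n_channels, "mu"),
            sigma=_channel_array(sigma, n_channels, "sigma"),
            sigma_bg=_channel_array(sigma_bg, n_channels, "sigma_bg"),
            num_timesteps=int(num_timesteps),
        )
        params.validate()
        return params

    def validate(self) -> None:
        for name in ("p", "m"):
            arr = getattr(self, name)
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} rates must lie in [0, 1]")
        for name, val in (("e", self.e), ("d", self.d)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if np.any(self.mu <= 0):
            raise ValueError("mu must be positive")
        if np.any(self.sigma <= 0) or np.any(self.sigma_bg <= 0):
            raise ValueError("sigma and sigma_bg must be positive")

    def replace(self, **kwargs) -> "SequencingParams":
        """Return a copy with some fields replaced (scalars broadcast)."""
        out = dict(kwargs)
        for name in ("p", "m", "mu", "sigma", "sigma_bg"):
            if name in out:
                out[name] = _channel_array(out[name], self.n_channels, name)
        new = replace(self, **out)
        new.validate()
        return new

    def cell_sd(self, lam: Scalarish) -> np.ndarray:
        """Per-channel intensity sd for ``lam`` surviving fluorophores.

        ``lam`` broadcasts against the channel axis (last axis = channel).
        """
        lam = np.asarray(lam, dtype=float)
        return np.sqrt(self.sigma_bg**2 + lam * self.sigma**2)
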