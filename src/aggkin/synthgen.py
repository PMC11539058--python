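"""Synthetic inputs for exercising every pipeline stage without external data.

Three generators are provided:

* :func:`condition_table_fixture` — the packaged 49-condition formulation table
  (temperature, ionic strength, pH, melting temperature, aggregation rate),
  shipped verbatim as CSV package data;
* :func:`synth_trajectory` — toy protein trajectories on a helix-like or
  random-coil backbone with planted per-residue Gaussian fluctuation
  amplitudes scaled by condition temperature, optionally decorated with
  charged pseudo side chains (ASP/GLU/LYS/ARG O/N atoms) so the
  salt-bridge and hydrogen-bond detectors have something to find;
* :func:`synth_feature_table` — condition-by-descriptor tables with planted
  low-rank linear structure X = F L + noise and response y = X beta + eps,
  returning the planted truth for recovery tests.

All generators are pure functions of their spec (the seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .descriptors import CANONICAL_FEATURES
from .trajio import ConditionTable, Trajectory, _make_record, read_condition_table

__all__ = [
    "TrajectorySpec",
    "FeatureTableSpec",
    "condition_table_fixture",
    "write_condition_fixture",
    "synth_trajectory",
    "synth_feature_table",
    "DEFAULT_TEMPERATURE_SCALE",
]

#: Fluctuation multiplier per condition temperature (K); hotter conditions
#: get proportionally larger planted amplitudes, mirroring the dominance of
#: temperature over the structural ensemble.
DEFAULT_TEMPERATURE_SCALE: dict[float, float] = {
    277.0: 0.8, 296.0: 1.0, 318.0: 1.4, 338.0: 2.0,
}


def condition_table_fixture() -> ConditionTable:
    """The packaged 49-condition formulation table, validated."""
    with resources.as_file(
        resources.files("aggkin.data") / "formulation_conditions.csv"
    ) as path:
        return read_condition_table(path)


def write_condition_fixture(path) -> None:
    """Copy the packaged 49-condition CSV to ``path``."""
    text = (resources.files("aggkin.data") / "formulation_conditions.csv"
            ).read_text()
    with open(path, "w") as fh:
        fh.write(text)


# ---------------------------------------------------------------------------
# trajectories

@dataclass
class TrajectorySpec:
    """Recipe for a synthetic trajectory.

    sigma_profile : per-residue fluctuation amplitude (Angstrom); a scalar
        is broadcast to all residues.
    temperature / temperature_scale : the condition temperature picks a
        sigma multiplier from the scale map (1.0 when absent).
    charged_sidechains : attach ASP/GLU/LYS/ARG pseudo side-chain O/N atoms
        at the given residue positions (1-based).
    """

    n_residues: int = 20
    n_frames: int = 50
    base_geometry: str = "helix"          # "helix" | "coil"
    sigma_profile: float | np.ndarray = 0.3
    temperature: float | None = None
    temperature_scale: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_TEMPERATURE_SCALE))
    charged_sidechains: dict[int, str] = field(default_factory=dict)
    frame_spacing_ns: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.base_geometry not in ("helix", "coil"):
            raise ValueError("base_geometry must be 'helix' or 'coil'")
        sig = np.broadcast_to(
            np.asarray(self.sigma_profile, dtype=float), (self.n_residues,)
        )
        if np.any(sig < 0):
            raise ValueError("sigma_profile must be non-negative")

    @property
    def sigma(self) -> np.ndarray:
        sig = np.broadcast_to(
            np.asarray(self.sigma_profile, dtype=float), (self.n_residues,)
        ).copy()
        if self.temperature is not None:
            sig *= self.temperature_scale.get(self.temperature, 1.0)
        return sig


_SIDECHAIN_ATOMS = {
    "ASP": [("CB", "C"), ("OD1", "O"), ("OD2", "O")],
    "GLU": [("CB", "C"), ("OE1", "O"), ("OE2", "O")],
    "LYS": [("CB", "C"), ("NZ", "N")],
    "ARG": [("CB", "C"), ("NE", "N"), ("NH1", "N")],
}


def _base_coordinates(spec: TrajectorySpec, rng: np.random.Generator
                      ) -> tuple[np.ndarray, list[tuple[str, str, int]]]:
    """Backbone CA positions plus (atom_name, element, residue) side chains."""
    n = spec.n_residues
    if spec.base_geometry == "helix":
        # alpha-helix-like spiral: 1.5 A rise, 100 degrees per residue
        t = np.arange(n)
        angle = np.deg2rad(100.0) * t
        ca = np.column_stack(
            [2.3 * np.cos(angle), 2.3 * np.sin(angle), 1.5 * t]
        )
    else:
        steps = rng.normal(size=(n, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        ca = np.cumsum(3.8 * steps, axis=0)
    atoms: list[tuple[str, str, int]] = []
    coords: list[np.ndarray] = []
    for i in range(n):
        res_id = i + 1
        atoms.append(("CA", "C", res_id))
        coords.append(ca[i])
        res_name = spec.charged_sidechains.get(res_id)
        if res_name:
            for k, (name, element) in enumerate(_SIDECHAIN_ATOMS[res_name]):
                offset = np.array([1.5 * (k + 1), 0.4 * k, 0.3])
                atoms.append((name, element, res_id))
                coords.append(ca[i] + offset)
    return np.array(coords), atoms


def synth_trajectory(spec: TrajectorySpec) -> Trajectory:
    """Generate a trajectory: base geometry plus per-atom Gaussian jitter
    with residue-specific amplitude times the temperature multiplier."""
    rng = np.random.default_rng(spec.seed)
    base, atoms = _base_coordinates(spec, rng)
    sigma = spec.sigma
    atom_sigma = np.array([sigma[res - 1] for _, _, res in atoms])
    noise = rng.normal(size=(spec.n_frames, base.shape[0], 3))
    coords = base[None, :, :] + atom_sigma[None, :, None] * noise
    topology = []
    for serial, (name, element, res_id) in enumerate(atoms, start=1):
        res_name = spec.charged_sidechains.get(res_id, "GLY")
        topology.append(
            _make_record(serial=serial, name=name, element=element,
                         res_name=res_name, res_index=res_id, chain_id="A")
        )
    times = spec.frame_spacing_ns * np.arange(spec.n_frames)
    return Trajectory(topology=topology, coordinates=coords, times=times)


# ---------------------------------------------------------------------------
# feature tables

@dataclass
class FeatureTableSpec:
    """Recipe for a feature table with planted low-rank linear structure.

    X = F L + E with F (n x r) standard-normal latent factors, L (r x p)
    loadings, and E Gaussian feature noise of sd ``noise_sd``.  The response
    is y = X beta + eps with eps sd equal to ``response_noise_frac`` times
    the sd of the noise-free signal X beta.
    """

    n_rows: int = 49
    feature_names: tuple[str, ...] = CANONICAL_FEATURES
    latent_rank: int = 2
    loadings: np.ndarray | None = None          # (latent_rank, p)
    response_coefficients: np.ndarray | None = None  # (p,)
    noise_sd: float = 0.0
    response_noise_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        p = len(self.feature_names)
        if not 1 <= self.latent_rank <= p:
            raise ValueError("latent_rank must be in [1, p]")
        if self.noise_sd < 0 or self.response_noise_frac < 0:
            raise ValueError("noise levels must be non-negative")
        if self.loadings is not None:
            L = np.asarray(self.loadings, dtype=float)
            if L.shape != (self.latent_rank, p):
                raise ValueError(f"loadings must be ({self.latent_rank}, {p})")


def synth_feature_table(spec: FeatureTableSpec
                        ) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Generate (features X, response y, planted truth record)."""
    rng = np.random.default_rng(spec.seed)
    p = len(spec.feature_names)
    r = spec.latent_rank
    L = (np.asarray(spec.loadings, dtype=float) if spec.loadings is not None
         else rng.normal(size=(r, p)))
    F = rng.normal(size=(spec.n_rows, r))
    X = F @ L
    if spec.noise_sd > 0:
        X = X + rng.normal(scale=spec.noise_sd, size=X.shape)
    beta = (np.asarray(spec.response_coefficients, dtype=float)
            if spec.response_coefficients is not None
            else rng.normal(size=p))
    signal = X @ beta
    y = signal.copy()
    if spec.response_noise_frac > 0:
        sd_signal = signal.std(ddof=0)
        y = y + rng.normal(scale=spec.response_noise_frac * sd_signal,
                           size=y.shape)
    index = pd.RangeIndex(1, spec.n_rows + 1, name="condition_id")
    table = pd.DataFrame(X, columns=list(spec.feature_names), index=index)
    response = pd.Series(y, index=index, name="ln_v")
    truth = {"beta_true": beta, "loadings": L, "latents": F,
             "signal": signal, "seed": spec.seed}
    return table, response, truth
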