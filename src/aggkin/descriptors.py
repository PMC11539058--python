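"""Molecular descriptors computed from trajectories.

Implements the 17 descriptors used to characterise an antibody fragment
across formulation conditions: total and nonpolar solvent-accessible
surface area (SASA), the SASA change of seven aggregation-prone regions
(APRs) and their sum, the fraction of native alpha-carbon contacts Q, mean
RMSF/RMSD/radius of gyration over the late trajectory window, hydrogen-bond
counts, Henderson-Hasselbalch net charge, and salt-bridge occurrence.

Late-window convention: production trajectories are analysed over their
final fraction (default half, i.e. the last 50 ns of a 100 ns run recorded
every 0.1 ns), and descriptor values are arithmetic means over replicate
runs of the same condition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajio import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "APRRegion",
    "DescriptorConfig",
    "PkaSite",
    "DEFAULT_APR_REGIONS",
    "CANONICAL_FEATURES",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_per_residue",
    "radius_of_gyration",
    "shrake_rupley_sasa",
    "total_sasa",
    "nonpolar_sasa",
    "delta_sasa_region",
    "hydrogen_bond_count",
    "salt_bridge_occurrence",
    "native_contact_fraction",
    "net_charge",
    "build_feature_table",
    "last_window_slice",
]


@dataclass(frozen=True)
class APRRegion:
    """An aggregation-prone region as an inclusive 1-based residue range."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid region {self.name}: {self.start}-{self.end}")

    def residue_indices(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)


#: The seven consensus APRs of Fab A33 on the continuous 1-442 numbering
#: (light chain 1-214, heavy chain 215-442).
DEFAULT_APR_REGIONS: tuple[APRRegion, ...] = (
    APRRegion("r_31-36", 31, 36),
    APRRegion("r_47-51", 47, 51),
    APRRegion("r_114-118", 114, 118),
    APRRegion("r_129-139", 129, 139),
    APRRegion("r_261-265", 261, 265),
    APRRegion("r_325-329", 325, 329),
    APRRegion("r_387-402", 387, 402),
)

#: Canonical descriptor column order of the feature table.
CANONICAL_FEATURES: tuple[str, ...] = (
    "Total SASA",
    "Nonpolar SASA",
    "r_31-36",
    "r_47-51",
    "r_114-118",
    "r_129-139",
    "r_261-265",
    "r_325-329",
    "r_387-402",
    "sum_aprsasa",
    "average native contact",
    "mean RMSF",
    "mean RMSD",
    "mean Rg",
    "number of hydrogen bonds",
    "net charges",
    "salt bridge average",
)


@dataclass
class DescriptorConfig:
    """Tunable parameters of the descriptor calculations.

    probe_radius : solvent probe radius for SASA, Angstrom (water, 1.4).
    sphere_points : mesh points per atom for the Shrake-Rupley surface.
    hbond_da_cutoff : donor-acceptor distance cutoff, Angstrom.
    hbond_angle_cutoff : H-donor-acceptor angle cutoff, degrees.
    saltbridge_cutoff : acidic-O to basic-N distance cutoff, Angstrom.
    native_cutoff : alpha-carbon contact cutoff for Q, Angstrom.
    last_window_fraction : final fraction of frames analysed as the
        "late window" (0.5 realises "last 50 ns" of a 100 ns run).
    baseline_frames : number of initial frames averaged as the SASA baseline.
    delta_sasa_single_frame_baseline : use only the 20th frame (1-based)
        instead of the first ``baseline_frames`` average.
    """

    probe_radius: float = 1.4
    sphere_points: int = 960
    hbond_da_cutoff: float = 3.5
    hbond_angle_cutoff: float = 30.0
    saltbridge_cutoff: float = 3.2
    native_cutoff: float = 8.0
    last_window_fraction: float = 0.5
    baseline_frames: int = 20
    delta_sasa_single_frame_baseline: bool = False
    native_sequence_exclusion: int = 0

    def __post_init__(self) -> None:
        for attr in ("probe_radius", "hbond_da_cutoff", "hbond_angle_cutoff",
                     "saltbridge_cutoff", "native_cutoff"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0")
        if not 0 < self.last_window_fraction < 1:
            raise ValueError("last_window_fraction must be in (0, 1)")
        if self.baseline_frames < 1:
            raise ValueError("baseline_frames must be >= 1")
        if self.sphere_points < 8:
            raise ValueError("sphere_points must be >= 8")


@dataclass(frozen=True)
class PkaSite:
    """One ionisable site: residue index, label, predicted pKa and class."""

    residue_index: int
    site_label: str
    pka: float
    site_class: str  # "acid" | "base"

    def __post_init__(self) -> None:
        if self.site_class not in ("acid", "base"):
            raise ValueError(f"site_class must be 'acid' or 'base', got "
                             f"{self.site_class!r}")

    def fractional_charge(self, pH: float) -> float:
        """Henderson-Hasselbalch fractional charge at the given pH."""
        if self.site_class == "base":
            return 1.0 / (1.0 + 10.0 ** (pH - self.pka))
        return -1.0 / (1.0 + 10.0 ** (self.pka - pH))


def last_window_slice(n_frames: int, fraction: float) -> slice:
    """Slice selecting the final ``fraction`` of ``n_frames`` (at least 1)."""
    start = min(n_frames - 1, int(np.ceil(n_frames * (1.0 - fraction))))
    return slice(start, n_frames)


# ---------------------------------------------------------------------------
# superposition / deviation / fluctuation

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None
                     ) -> tuple[np.ndarray, float]:
    """Optimally superpose ``mobile`` onto ``reference``.

    Returns the transformed coordinates and the weighted RMSD after the
    optimal proper rotation + translation (reflections are excluded by the
    determinant sign correction of the SVD solution).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be N x 3")
    n = mobile.shape[0]
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("weights must have one entry per atom")
        if not np.any(w > 0):
            raise ValueError("weights must not be all zero")
    wsum = w.sum()
    mob_c = (w[:, None] * mobile).sum(axis=0) / wsum
    ref_c = (w[:, None] * reference).sum(axis=0) / wsum
    P = mobile - mob_c
    Q = reference - ref_c
    H = (w[:, None] * P).T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    rotated = P @ R.T + ref_c
    diff = rotated - reference
    rmsd = float(np.sqrt((w * (diff ** 2).sum(axis=1)).sum() / wsum))
    return rotated, rmsd


def rmsd_series(traj: Trajectory, reference_frame_index: int = 0,
                selection: np.ndarray | None = None,
                superpose: bool = True) -> np.ndarray:
    """Per-frame RMSD (Angstrom) relative to a reference frame.

    Each frame is superposed onto the reference before the deviation is
    measured, so rigid-body motion does not register as deviation.
    ``selection`` is an array of 0-based atom indices (default: all atoms).
    """
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    if sel.size == 0:
        raise ValueError("empty atom selection")
    ref = traj.coordinates[reference_frame_index][sel]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        frame = traj.coordinates[f][sel]
        if superpose:
            _, out[f] = kabsch_superpose(frame, ref)
        else:
            out[f] = float(np.sqrt(((frame - ref) ** 2).sum(axis=1).mean()))
    return out


def _one_atom_per_residue(traj: Trajectory, sel: np.ndarray) -> np.ndarray:
    res = traj.residue_indices[sel]
    uniq, counts = np.unique(res, return_counts=True)
    bad = uniq[counts != 1]
    if bad.size:
        raise ValueError(
            f"selection must have exactly one atom per residue; residues "
            f"{bad.tolist()} have {counts[counts != 1].tolist()} atoms"
        )
    return res


def rmsf_per_residue(traj: Trajectory, selection: np.ndarray | None = None,
                     config: DescriptorConfig | None = None,
                     superpose: bool = True,
                     use_last_window: bool = True) -> pd.Series:
    """Per-residue root-mean-square fluctuation (Angstrom).

    Defaults to one alpha-carbon per residue.  Frames are first superposed
    onto the reference frame, the time-average structure is computed, and a
    second superposition pass aligns every frame onto that mean before the
    fluctuation about the mean position is measured (the common two-pass
    convention).  Restricted to the late trajectory window by default.
    """
    config = config or DescriptorConfig()
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    if selection is None:
        selection = traj.atom_indices(name="CA")
        if selection.size == 0:
            raise ValueError("no alpha-carbons found; pass an explicit selection")
    sel = np.asarray(selection)
    res = _one_atom_per_residue(traj, sel)
    window = (last_window_slice(traj.n_frames, config.last_window_fraction)
              if use_last_window else slice(None))
    frames = traj.coordinates[window][:, sel, :]

    if superpose:
        ref = frames[0]
        pass1 = np.stack([kabsch_superpose(f, ref)[0] for f in frames])
        mean1 = pass1.mean(axis=0)
        aligned = np.stack([kabsch_superpose(f, mean1)[0] for f in frames])
    else:
        aligned = frames
    mean = aligned.mean(axis=0)
    fluct = np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))
    return pd.Series(fluct, index=pd.Index(res, name="residue_index"),
                     name="rmsf")


def radius_of_gyration(traj: Trajectory) -> np.ndarray:
    """Mass-weighted radius of gyration per frame (Angstrom)."""
    m = traj.masses
    if m.sum() <= 0:
        raise ValueError("total mass must be positive")
    com = (m[:, None] * traj.coordinates).sum(axis=1) / m.sum()
    d2 = ((traj.coordinates - com[:, None, :]) ** 2).sum(axis=2)
    return np.sqrt((m * d2).sum(axis=1) / m.sum())


# ---------------------------------------------------------------------------
# solvent-accessible surface area (Shrake-Rupley)

def _golden_spiral(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere mesh via the golden-angle spiral."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def shrake_rupley_sasa(coords: np.ndarray, radii: np.ndarray,
                       subset: np.ndarray | None = None,
                       probe_radius: float = 1.4,
                       sphere_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area by the Shrake-Rupley rolling
    probe construction.

    Each atom's extended sphere (vdW radius + probe) is covered with a
    quasi-uniform mesh; a mesh point is solvent-accessible iff it lies
    outside every other atom's extended sphere.  All atoms in ``coords``
    occlude; areas are reported for ``subset`` (default: all).
    Returns Angstrom^2 per subset atom.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.shape[0] != radii.shape[0]:
        raise ValueError("one radius per atom required")
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        raise ValueError("all atoms need a positive vdW radius")
    subset = np.arange(coords.shape[0]) if subset is None else np.asarray(subset)
    mesh = _golden_spiral(sphere_points)
    ext = radii + probe_radius
    tree = cKDTree(coords)
    max_ext = ext.max()
    areas = np.zeros(subset.shape[0])
    for out_i, i in enumerate(subset):
        r_i = ext[i]
        pts = coords[i] + r_i * mesh
        neighbors = tree.query_ball_point(coords[i], r_i + max_ext)
        neighbors = [j for j in neighbors if j != i]
        accessible = np.ones(sphere_points, dtype=bool)
        for j in neighbors:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > ext[j] ** 2
            if not accessible.any():
                break
        areas[out_i] = 4.0 * np.pi * r_i ** 2 * accessible.mean()
    return areas


def _heavy(traj: Trajectory) -> np.ndarray:
    return traj.atom_indices(heavy_only=True)


def total_sasa(traj: Trajectory, frame: int = 0,
               config: DescriptorConfig | None = None) -> float:
    """Total SASA of the heavy atoms in one frame (hydrogens excluded from
    both the reported subset and the occluding universe)."""
    config = config or DescriptorConfig()
    heavy = _heavy(traj)
    coords = traj.coordinates[frame][heavy]
    radii = traj.vdw_radii[heavy]
    return float(shrake_rupley_sasa(coords, radii, None, config.probe_radius,
                                    config.sphere_points).sum())


def nonpolar_sasa(traj: Trajectory, frame: int = 0,
                  config: DescriptorConfig | None = None) -> float:
    """Carbon-atom SASA in one frame (heavy atoms occlude)."""
    config = config or DescriptorConfig()
    heavy = _heavy(traj)
    coords = traj.coordinates[frame][heavy]
    radii = traj.vdw_radii[heavy]
    carbon = np.nonzero(traj.elements[heavy] == "C")[0]
    if carbon.size == 0:
        return 0.0
    return float(shrake_rupley_sasa(coords, radii, carbon, config.probe_radius,
                                    config.sphere_points).sum())


def _region_sasa_series(traj: Trajectory, region: APRRegion,
                        config: DescriptorConfig,
                        frames: np.ndarray) -> np.ndarray:
    heavy = _heavy(traj)
    radii = traj.vdw_radii[heavy]
    res = traj.residue_indices[heavy]
    in_region = np.nonzero((res >= region.start) & (res <= region.end))[0]
    if in_region.size == 0:
        raise ValueError(f"region {region.name}: no residues present")
    out = np.empty(frames.shape[0])
    for k, f in enumerate(frames):
        coords = traj.coordinates[f][heavy]
        out[k] = shrake_rupley_sasa(coords, radii, in_region,
                                    config.probe_radius,
                                    config.sphere_points).sum()
    return out


def delta_sasa_region(replicates: list[Trajectory], region: APRRegion,
                      config: DescriptorConfig | None = None) -> float:
    """Late-window SASA of an APR minus its early baseline, replicate-averaged.

    Per replicate: mean region SASA over the late window minus the mean over
    the first ``baseline_frames`` frames (or, with the single-frame option,
    the SASA at the ``baseline_frames``-th frame alone).
    """
    config = config or DescriptorConfig()
    vals = []
    for traj in replicates:
        if traj.n_frames < config.baseline_frames:
            raise ValueError(
                f"trajectory has {traj.n_frames} frames, fewer than the "
                f"{config.baseline_frames}-frame baseline"
            )
        window = last_window_slice(traj.n_frames, config.last_window_fraction)
        late_frames = np.arange(traj.n_frames)[window]
        late = _region_sasa_series(traj, region, config, late_frames).mean()
        if config.delta_sasa_single_frame_baseline:
            base_frames = np.array([config.baseline_frames - 1])
        else:
            base_frames = np.arange(min(config.baseline_frames, traj.n_frames))
        base = _region_sasa_series(traj, region, config, base_frames).mean()
        vals.append(late - base)
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# hydrogen bonds

def _find_donor_hydrogens(traj: Trajectory, frame: int,
                          donors: np.ndarray) -> dict[int, list[int]]:
    """Hydrogens covalently bound to each donor (distance <= 1.25 A)."""
    hyd = traj.atom_indices(element="H")
    bound: dict[int, list[int]] = {int(d): [] for d in donors}
    if hyd.size == 0:
        return bound
    coords = traj.coordinates[frame]
    tree = cKDTree(coords[hyd])
    for d in donors:
        near = tree.query_ball_point(coords[d], 1.25)
        bound[int(d)] = [int(hyd[j]) for j in near]
    return bound


def hydrogen_bond_count(traj: Trajectory,
                        config: DescriptorConfig | None = None,
                        use_last_window: bool = False) -> np.ndarray:
    """Hydrogen bonds per frame under a geometric criterion.

    A bond is counted when an N/O donor carrying a hydrogen lies within
    ``hbond_da_cutoff`` of an N/O acceptor and the H-donor-acceptor angle is
    at most ``hbond_angle_cutoff`` (the GROMACS convention, 3.5 A / 30 deg).
    Intra-residue pairs are excluded.  Models without hydrogens fall back to
    distance-only counting with a warning.
    """
    config = config or DescriptorConfig()
    els = traj.elements
    no_atoms = np.nonzero((els == "N") | (els == "O"))[0]
    frames_all = (np.arange(traj.n_frames)[last_window_slice(
        traj.n_frames, config.last_window_fraction)]
        if use_last_window else np.arange(traj.n_frames))
    if no_atoms.size == 0:
        warnings.warn("no N/O atoms: hydrogen-bond count is 0", stacklevel=2)
        return np.zeros(frames_all.shape[0], dtype=int)
    has_h = traj.atom_indices(element="H").size > 0
    if not has_h:
        warnings.warn(
            "model carries no hydrogens; falling back to distance-only "
            "hydrogen-bond counting", stacklevel=2,
        )
    res = traj.residue_indices
    frames = frames_all
    counts = np.zeros(frames.shape[0], dtype=int)
    cos_cut = np.cos(np.deg2rad(config.hbond_angle_cutoff))
    for k, f in enumerate(frames):
        coords = traj.coordinates[f]
        tree = cKDTree(coords[no_atoms])
        pairs = tree.query_pairs(config.hbond_da_cutoff, output_type="ndarray")
        if pairs.size == 0:
            continue
        a = no_atoms[pairs[:, 0]]
        b = no_atoms[pairs[:, 1]]
        inter = res[a] != res[b]
        a, b = a[inter], b[inter]
        if not has_h:
            counts[k] = a.size
            continue
        bound = _find_donor_hydrogens(traj, f, no_atoms)
        n_bonds = 0
        for d, acc in list(zip(a, b)) + list(zip(b, a)):
            hs = bound.get(int(d), [])
            if not hs:
                continue
            v_da = coords[acc] - coords[d]
            ok = False
            for h in hs:
                v_dh = coords[h] - coords[d]
                denom = np.linalg.norm(v_da) * np.linalg.norm(v_dh)
                if denom == 0:
                    continue
                if np.dot(v_da, v_dh) / denom >= cos_cut:
                    ok = True
                    break
            if ok:
                n_bonds += 1
        counts[k] = n_bonds
    return counts


# ---------------------------------------------------------------------------
# salt bridges

_ACIDIC_O = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_BASIC_N = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}


def _charged_atoms(traj: Trajectory) -> tuple[list[tuple[int, int]],
                                              list[tuple[int, int]]]:
    """(residue_index, atom_index) lists of acidic O and basic N atoms."""
    acidic, basic = [], []
    for i, a in enumerate(traj.topology):
        if a.residue_name in _ACIDIC_O and a.name in _ACIDIC_O[a.residue_name]:
            acidic.append((a.residue_index, i))
        elif a.residue_name in _BASIC_N and a.name in _BASIC_N[a.residue_name]:
            basic.append((a.residue_index, i))
    return acidic, basic


def salt_bridge_occurrence(replicates: list[Trajectory],
                           config: DescriptorConfig | None = None
                           ) -> tuple[pd.DataFrame, float]:
    """Salt-bridge occurrence per acidic/basic residue pair, and the scalar
    average descriptor.

    A pair enters the universe if the minimum distance between any acidic
    side-chain oxygen (ASP/GLU) and basic side-chain nitrogen (ARG/LYS) is
    within the cutoff in at least one late-window frame; its occurrence is
    the percentage of late-window frames satisfying the criterion.  The
    scalar descriptor is the mean occurrence over pairs, then over
    replicates.
    """
    config = config or DescriptorConfig()
    rows = []
    rep_means = []
    for rep_no, traj in enumerate(replicates, start=1):
        acidic, basic = _charged_atoms(traj)
        window = last_window_slice(traj.n_frames, config.last_window_fraction)
        frames = np.arange(traj.n_frames)[window]
        pair_frame_hits: dict[tuple[int, int], int] = {}
        if acidic and basic:
            a_res = np.array([r for r, _ in acidic])
            a_idx = np.array([i for _, i in acidic])
            b_res = np.array([r for r, _ in basic])
            b_idx = np.array([i for _, i in basic])
            for f in frames:
                coords = traj.coordinates[f]
                d = np.linalg.norm(
                    coords[a_idx][:, None, :] - coords[b_idx][None, :, :],
                    axis=2,
                )
                hit = d <= config.saltbridge_cutoff
                seen: set[tuple[int, int]] = set()
                for ai, bi in zip(*np.nonzero(hit)):
                    key = (int(a_res[ai]), int(b_res[bi]))
                    if key not in seen:
                        pair_frame_hits[key] = pair_frame_hits.get(key, 0) + 1
                        seen.add(key)
            for (ra, rb), nhit in sorted(pair_frame_hits.items()):
                occ = 100.0 * nhit / frames.shape[0]
                rows.append({"replicate": rep_no, "acidic_residue": ra,
                             "basic_residue": rb, "occurrence_pct": occ})
        occs = [100.0 * n / frames.shape[0] for n in pair_frame_hits.values()]
        if not occs:
            warnings.warn(
                f"replicate {rep_no}: empty salt-bridge universe",
                stacklevel=2,
            )
            rep_means.append(0.0)
        else:
            rep_means.append(float(np.mean(occs)))
    table = pd.DataFrame(
        rows, columns=["replicate", "acidic_residue", "basic_residue",
                       "occurrence_pct"],
    )
    return table, float(np.mean(rep_means)) if rep_means else 0.0


# ---------------------------------------------------------------------------
# native contacts

def native_contact_fraction(traj: Trajectory, reference_frame_index: int = 0,
                            config: DescriptorConfig | None = None
                            ) -> np.ndarray:
    """Per-frame fraction Q of reference alpha-carbon contacts preserved.

    The reference contact set contains every distinct-residue CA pair within
    ``native_cutoff`` (8 A) in the reference frame; Q(t) is the fraction of
    those pairs still within the cutoff at frame t.
    """
    config = config or DescriptorConfig()
    ca = traj.atom_indices(name="CA")
    if ca.size < 4:
        raise ValueError("need at least 4 alpha-carbons for native contacts")
    res = traj.residue_indices[ca]
    ref = traj.coordinates[reference_frame_index][ca]
    tree = cKDTree(ref)
    pairs = tree.query_pairs(config.native_cutoff, output_type="ndarray")
    if pairs.size:
        distinct = res[pairs[:, 0]] != res[pairs[:, 1]]
        if config.native_sequence_exclusion > 0:
            distinct &= (np.abs(res[pairs[:, 0]] - res[pairs[:, 1]])
                         > config.native_sequence_exclusion)
        pairs = pairs[distinct]
    if pairs.shape[0] == 0:
        raise ValueError("empty native-contact set in the reference frame")
    i, j = pairs[:, 0], pairs[:, 1]
    q = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        coords = traj.coordinates[f][ca]
        d = np.linalg.norm(coords[i] - coords[j], axis=1)
        q[f] = float(np.mean(d <= config.native_cutoff))
    return q


# ---------------------------------------------------------------------------
# net charge

def net_charge(pka_sites: list[PkaSite], pH: float) -> float:
    """Henderson-Hasselbalch net charge (elementary charges) at a given pH.

    Z = sum over bases of 1/(1+10^(pH-pKa)) minus sum over acids of
    1/(1+10^(pKa-pH)).
    """
    if not 0 < pH < 14:
        raise ValueError(f"pH must be in (0, 14), got {pH}")
    if not pka_sites:
        warnings.warn("empty pKa site list: net charge is 0", stacklevel=2)
        return 0.0
    return float(sum(s.fractional_charge(pH) for s in pka_sites))


# ---------------------------------------------------------------------------
# assembly

def _mean_over_window(series: np.ndarray, fraction: float) -> float:
    return float(series[last_window_slice(series.shape[0], fraction)].mean())


def build_feature_table(replicates_by_condition: dict[int, list[Trajectory]],
                        pka_by_condition: dict[int, list[PkaSite]],
                        pH_by_condition: dict[int, float],
                        regions: tuple[APRRegion, ...] = DEFAULT_APR_REGIONS,
                        config: DescriptorConfig | None = None,
                        strict: bool = False
                        ) -> tuple[pd.DataFrame, dict]:
    """Assemble the full condition x 17-descriptor feature table.

    Parameters
    ----------
    replicates_by_condition : replicate trajectories per condition id.
    pka_by_condition : per-condition ionisable-site tables (plain inputs;
        no pKa predictor is invoked).
    pH_by_condition : solution pH per condition.

    Returns the table (rows keyed by condition id, the 17 canonical columns)
    and a provenance record (replicate counts, window bounds, failures).
    Descriptor failures leave the cell as NaN; in strict mode they raise.
    """
    config = config or DescriptorConfig()
    rows = {}
    provenance: dict = {"window_fraction": config.last_window_fraction,
                        "conditions": {}, "failures": []}
    for cond_id, reps in sorted(replicates_by_condition.items()):
        if not reps:
            raise ValueError(f"condition {cond_id}: no replicate trajectories")
        row: dict[str, float] = {}

        def _compute(name: str, fn) -> None:
            try:
                row[name] = float(fn())
            except Exception as exc:  # noqa: BLE001 - cell-level isolation
                if strict:
                    raise
                provenance["failures"].append(
                    {"condition": cond_id, "feature": name, "error": str(exc)}
                )
                row[name] = np.nan

        frac = config.last_window_fraction
        _compute("Total SASA", lambda: np.mean(
            [total_sasa(t, t.n_frames - 1, config) for t in reps]))
        _compute("Nonpolar SASA", lambda: np.mean(
            [nonpolar_sasa(t, t.n_frames - 1, config) for t in reps]))
        for region in regions:
            _compute(region.name,
                     lambda r=region: delta_sasa_region(reps, r, config))
        if all(np.isfinite(row.get(r.name, np.nan)) for r in regions):
            row["sum_aprsasa"] = float(sum(row[r.name] for r in regions))
        else:
            row["sum_aprsasa"] = np.nan
        _compute("average native contact", lambda: np.mean(
            [_mean_over_window(native_contact_fraction(t, 0, config), frac)
             for t in reps]))
        _compute("mean RMSF", lambda: np.mean(
            [rmsf_per_residue(t, config=config).mean() for t in reps]))
        _compute("mean RMSD", lambda: np.mean(
            [_mean_over_window(rmsd_series(t), frac) for t in reps]))
        _compute("mean Rg", lambda: np.mean(
            [_mean_over_window(radius_of_gyration(t), frac) for t in reps]))
        _compute("number of hydrogen bonds", lambda: np.mean(
            [hydrogen_bond_count(t, config, use_last_window=True).mean()
             for t in reps]))
        _compute("net charges", lambda: net_charge(
            pka_by_condition.get(cond_id, []), pH_by_condition[cond_id]))
        _compute("salt bridge average",
                 lambda: salt_bridge_occurrence(reps, config)[1])
        rows[cond_id] = row
        provenance["conditions"][cond_id] = {
            "n_replicates": len(reps),
            "n_frames": [t.n_frames for t in reps],
        }
    # canonical column order; non-default region sets substitute their names
    # in place of the seven canonical r_* windows (a "partial" table)
    default_names = {r.name for r in DEFAULT_APR_REGIONS}
    columns: list[str] = []
    for name in CANONICAL_FEATURES:
        if name in default_names:
            continue
        if name == "sum_aprsasa":
            columns.extend(r.name for r in regions)
        columns.append(name)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table[columns]
    table.index.name = "condition_id"
    return table, provenance
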