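"""Selectivity-filter geometry and steered-pull analysis of channel trajectories.

Works on coordinate trajectories of a fourfold-symmetric K+ channel
(chains A-D, Shaker residue numbering).  The filter metrics follow the
opposing-subunit convention: for a residue position, the "diameter" is the
average of the two opposing-chain distances (A-C and B-D) between the
chosen atoms — backbone carbonyl oxygens for the filter diameter, alpha
carbons for the backbone series.  The steered-pull coordinate is the
center-of-mass distance between residue 416 of opposing subunits,
restrained harmonically to a reference that moves outward at a constant
rate; each residue therefore drifts centrifugally at half the reference
rate.

Internal length unit is nm (PDB I/O converts from Angstrom).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "Frame",
    "PullSchedule",
    "DiameterSeries",
    "IonOccupancy",
    "read_trajectory",
    "write_trajectory",
    "com_pair_distance",
    "pull_force",
    "align_to_reference",
    "filter_diameter",
    "filter_diameter_series",
    "ca_distance_series",
    "carbonyl_displacement_stats",
    "detect_collapse",
    "ion_occupancy",
]

# monoisotopic-ish masses for the atoms that occur in these models
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "K": 39.098,
    "NA": 22.990,
    "CL": 35.45,
}

OPPOSING_PAIRS = (("A", "C"), ("B", "D"))
FILTER_POSITIONS = (443, 444, 445, 446)
ALIGN_POSITIONS = tuple(range(441, 447))
ALIGN_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class Frame:
    """One trajectory frame: flat atom records with coordinates in nm."""

    chain_id: np.ndarray  # str per atom ('A'..'D', or '' for ions)
    res_id: np.ndarray  # int, Shaker numbering
    res_name: np.ndarray  # str
    atom_name: np.ndarray  # str
    element: np.ndarray  # str, keys of ATOMIC_MASSES
    coords: np.ndarray  # (n_atoms, 3) nm
    frame_time: float = 0.0  # ns

    def __post_init__(self) -> None:
        n = len(self.coords)
        for name in ("chain_id", "res_id", "res_name", "atom_name", "element"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match coordinates")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("frame contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.coords)

    def select(
        self,
        chain: str | None = None,
        res_id: int | None = None,
        atom_name: str | None = None,
        element: str | None = None,
    ) -> np.ndarray:
        """Boolean mask over atoms matching all given criteria."""
        mask = np.ones(len(self), dtype=bool)
        if chain is not None:
            mask &= self.chain_id == chain
        if res_id is not None:
            mask &= self.res_id == res_id
        if atom_name is not None:
            mask &= self.atom_name == atom_name
        if element is not None:
            mask &= self.element == element
        return mask

    def masses(self) -> np.ndarray:
        try:
            return np.array([ATOMIC_MASSES[e] for e in self.element])
        except KeyError as err:
            raise ValueError(f"unknown element {err.args[0]!r}") from None


@dataclass(frozen=True)
class PullSchedule:
    """Harmonic pull on the opposing-pair distance with a moving reference.

    ``force_constant`` in kJ/mol/nm^2, ``rate`` (reference growth) in nm/ns,
    ``reference_0`` the initial pair distance in nm.  Because the restrained
    coordinate is the distance *between* the two residues, each residue
    moves outward at ``rate / 2``.
    """

    force_constant: float  # kJ/mol/nm^2
    rate: float  # nm/ns
    reference_0: float  # nm

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        if not np.isfinite(self.rate):
            raise ValueError("rate must be finite")

    @property
    def per_residue_speed(self) -> float:
        return self.rate / 2.0


@dataclass(frozen=True)
class DiameterSeries:
    """Per-position time series of opposing-pair mean distances (nm)."""

    position: int
    times: np.ndarray  # ns
    diameters: np.ndarray  # nm

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "diameters", np.asarray(self.diameters, dtype=float))
        if len(self.times) != len(self.diameters):
            raise ValueError("times and diameters differ in length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        if np.any(self.diameters <= 0):
            raise ValueError("diameters must be positive")


@dataclass(frozen=True)
class IonOccupancy:
    counts: np.ndarray  # per-frame ion count in the filter cylinder
    departure_frame: int | None  # first persistent drop below the initial count


def _element_from_atom(atom_name: str, res_name: str) -> str:
    if res_name in ("K", "POT") or atom_name == "K":
        return "K"
    if res_name in ("NA", "SOD") or atom_name == "NA":
        return "NA"
    return atom_name[0]


def read_trajectory(path: str | Path) -> list[Frame]:
    """Read a multi-model PDB into a list of frames (coordinates in nm).

    Frame times are taken as the model index in ns when no time metadata is
    present, matching the 1 frame/ns convention of the synthetic trajectories.
    """
    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    elements = np.array(
        [
            e if e in ATOMIC_MASSES else _element_from_atom(an, rn)
            for e, an, rn in zip(stack.element, stack.atom_name, stack.res_name)
        ]
    )
    frames = []
    for i in range(stack.stack_depth()):
        frames.append(
            Frame(
                chain_id=np.asarray(stack.chain_id),
                res_id=np.asarray(stack.res_id),
                res_name=np.asarray(stack.res_name),
                atom_name=np.asarray(stack.atom_name),
                element=elements,
                coords=np.asarray(stack.coord[i], dtype=float) / 10.0,  # A -> nm
                frame_time=float(i),
            )
        )
    return frames


def write_trajectory(frames: list[Frame], path: str | Path) -> None:
    """Write frames as a multi-model PDB (MODEL records indexed from 1).

    All frames must share the same atom table; coordinates are converted
    from nm to Angstrom.  Occupancy/B-factor columns are written as
    1.00/0.00.
    """
    if not frames:
        raise ValueError("no frames to write")
    first = frames[0]
    n = len(first)
    template = struc.AtomArray(n)
    template.chain_id = first.chain_id
    template.res_id = first.res_id
    template.res_name = first.res_name
    template.atom_name = first.atom_name
    template.element = first.element
    template.hetero = np.isin(first.element, ["K", "NA", "CL"])
    template.add_annotation("occupancy", dtype=float)
    template.add_annotation("b_factor", dtype=float)
    template.occupancy = np.ones(n)
    template.b_factor = np.zeros(n)
    coords = np.stack([f.coords for f in frames]) * 10.0  # nm -> A
    stack = struc.from_template(template, coords)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def _residue_com(frame: Frame, chain: str, res_id: int) -> np.ndarray:
    mask = frame.select(chain=chain, res_id=res_id)
    if not mask.any():
        raise ValueError(f"residue {res_id} missing in chain {chain}")
    m = frame.masses()[mask]
    return (frame.coords[mask] * m[:, None]).sum(axis=0) / m.sum()


def com_pair_distance(
    frame: Frame,
    residue: int,
    pairing: tuple[tuple[str, str], ...] = OPPOSING_PAIRS,
) -> tuple[float, ...]:
    """Mass-weighted COM distance of a residue between opposing chains."""
    out = []
    for c1, c2 in pairing:
        d = np.linalg.norm(_residue_com(frame, c1, residue) - _residue_com(frame, c2, residue))
        out.append(float(d))
    return tuple(out)


def pull_force(
    schedule: PullSchedule, time: float, current_distance: float
) -> tuple[float, float]:
    """Restraint force (kJ/mol/nm) and reference distance (nm) at a time.

    ``reference(t) = reference_0 + rate * t``;
    ``force = k * (reference(t) - current_distance)`` — positive force pulls
    the pair apart (current distance lags the reference).
    """
    if time < 0:
        raise ValueError("time must be >= 0")
    reference = schedule.reference_0 + schedule.rate * time
    force = schedule.force_constant * (reference - current_distance)
    return float(force), float(reference)


def _alignment_selection(frame: Frame, residues, atom_names, chains=("A", "B", "C", "D")) -> np.ndarray:
    idx = []
    for chain in chains:
        for res in residues:
            for name in atom_names:
                mask = frame.select(chain=chain, res_id=res, atom_name=name)
                found = np.nonzero(mask)[0]
                if len(found) != 1:
                    raise ValueError(
                        f"alignment selection: atom {name} of residue {res} chain "
                        f"{chain} {'missing' if len(found) == 0 else 'duplicated'}"
                    )
                idx.append(found[0])
    return np.array(idx)


def align_to_reference(
    frame: Frame,
    reference: Frame,
    residues=ALIGN_POSITIONS,
    atom_names=ALIGN_ATOMS,
) -> tuple[Frame, float]:
    """Rigid-body superposition onto a reference frame (Kabsch).

    The optimal rotation + translation (proper rotation only, no
    reflection) is computed over the backbone N, CA, C, O atoms of the
    filter residues in all four chains and applied to every atom of the
    frame.  Returns the aligned frame and the RMSD over the selection.
    """
    idx_mob = _alignment_selection(frame, residues, atom_names)
    idx_ref = _alignment_selection(reference, residues, atom_names)
    x = frame.coords[idx_mob]
    y = reference.coords[idx_ref]

    xc, yc = x.mean(axis=0), y.mean(axis=0)
    h = (x - xc).T @ (y - yc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T

    new_coords = (frame.coords - xc) @ rot.T + yc
    rmsd = float(np.sqrt(np.mean(np.sum((new_coords[idx_mob] - y) ** 2, axis=1))))
    return replace(frame, coords=new_coords), rmsd


def _pair_mean_distance(frame: Frame, position: int, atom_name: str) -> float:
    dists = []
    for c1, c2 in OPPOSING_PAIRS:
        pts = []
        for chain in (c1, c2):
            mask = frame.select(chain=chain, res_id=position, atom_name=atom_name)
            found = np.nonzero(mask)[0]
            if len(found) == 0:
                raise ValueError(
                    f"atom {atom_name} of residue {position} missing in chain {chain}"
                )
            pts.append(frame.coords[found[0]])
        dists.append(np.linalg.norm(pts[0] - pts[1]))
    return float(np.mean(dists))


def filter_diameter(frame: Frame, position: int) -> float:
    """Filter diameter at a position: mean opposing carbonyl-O distance (nm)."""
    return _pair_mean_distance(frame, position, "O")


def filter_diameter_series(trajectory: list[Frame], position: int) -> DiameterSeries:
    """Carbonyl-O diameter of one filter position along a trajectory."""
    times = np.array([f.frame_time for f in trajectory])
    diam = np.array([filter_diameter(f, position) for f in trajectory])
    return DiameterSeries(position=position, times=times, diameters=diam)


def ca_distance_series(
    trajectory: list[Frame], positions=ALIGN_POSITIONS
) -> dict[int, DiameterSeries]:
    """Opposing-chain alpha-carbon mean distances per position over time."""
    times = np.array([f.frame_time for f in trajectory])
    out = {}
    for pos in positions:
        diam = np.array([_pair_mean_distance(f, pos, "CA") for f in trajectory])
        out[pos] = DiameterSeries(position=pos, times=times, diameters=diam)
    return out


def carbonyl_displacement_stats(
    trajectory: list[Frame],
    positions=(443, 444, 445),
    reference: Frame | None = None,
) -> tuple[float, float]:
    """Mean |displacement| of opposing carbonyl distances from a reference.

    For every frame and position the carbonyl-O diameter is compared with
    the reference frame (default: the first frame); the statistic is the
    mean absolute displacement and its standard error across all
    frame x position samples.  Used as the no-perturbation control check.
    """
    if len(trajectory) < 2:
        raise ValueError("need at least 2 frames")
    if reference is None:
        reference = trajectory[0]
    ref = {p: filter_diameter(reference, p) for p in positions}
    disps = np.array(
        [
            abs(filter_diameter(f, p) - ref[p])
            for f in trajectory
            for p in positions
        ]
    )
    mean = float(disps.mean())
    se = float(disps.std(ddof=1) / np.sqrt(len(disps)))
    return mean, se


def detect_collapse(
    series: DiameterSeries, threshold: float = 0.05, window: int = 10
) -> int | None:
    """First frame of a persistent diameter change from baseline.

    Baseline is the median of the first ``window`` frames; a collapse (or
    dilation) is the first frame whose |diameter - baseline| exceeds
    ``threshold`` and keeps exceeding it for at least ``window`` consecutive
    frames.  Returns None when no such event exists.
    """
    n = len(series.diameters)
    if n < 2 * window:
        raise ValueError(f"need at least {2 * window} frames, got {n}")
    baseline = float(np.median(series.diameters[:window]))
    exceed = np.abs(series.diameters - baseline) > threshold
    run = 0
    for i in range(n):
        run = run + 1 if exceed[i] else 0
        if run == window:
            return i - window + 1
    return None


def _filter_cylinder(frame: Frame, radius: float, z_margin: float):
    """Axis center (xy), z-bounds and radius of the filter region."""
    coords = []
    for pos in FILTER_POSITIONS:
        for chain in ("A", "B", "C", "D"):
            mask = frame.select(chain=chain, res_id=pos, atom_name="O")
            found = np.nonzero(mask)[0]
            if len(found):
                coords.append(frame.coords[found[0]])
    if not coords:
        raise ValueError("no filter carbonyl oxygens found")
    coords = np.array(coords)
    center_xy = coords[:, :2].mean(axis=0)
    z_lo = coords[:, 2].min() - z_margin
    z_hi = coords[:, 2].max() + z_margin
    return center_xy, z_lo, z_hi, radius


def ion_occupancy(
    trajectory: list[Frame],
    ion: str = "K",
    radius: float = 0.4,
    z_margin: float = 0.1,
    window: int = 5,
) -> IonOccupancy:
    """Count ions inside the filter cylinder per frame; detect first departure.

    The cylinder is built per frame from the carbonyl-O rings of the filter
    positions: axis through their mean xy, z-range spanning the rings plus a
    margin.  The departure frame is the first frame where the count drops
    below its initial value and stays below for >= ``window`` frames.
    """
    ion = ion.upper()
    counts = []
    for frame in trajectory:
        ions = frame.select(element=ion)
        if not ions.any():
            raise ValueError(f"no {ion} ions present in the model")
        center_xy, z_lo, z_hi, r = _filter_cylinder(frame, radius, z_margin)
        xyz = frame.coords[ions]
        radial = np.linalg.norm(xyz[:, :2] - center_xy, axis=1)
        inside = (radial <= r) & (xyz[:, 2] >= z_lo) & (xyz[:, 2] <= z_hi)
        counts.append(int(inside.sum()))
    counts = np.array(counts)
    below = counts < counts[0]
    departure = None
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= window:
            departure = i - window + 1
            break
    return IonOccupancy(counts=counts, departure_frame=departure)
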