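"""Analytic EEG forward model: concentric multi-shell sphere.

The head is modelled as five concentric homogeneous spheres (white matter,
gray matter, CSF, skull, scalp).  For a current dipole inside the innermost
shell the scalp potential is expanded in Legendre series; the per-degree
radial gain through the shell stack is obtained from 2x2 transfer matrices
that encode continuity of potential and radial current at each interface.

All coordinates are meters in a right-handed head frame (x right, y anterior,
z superior) with origin at the sphere centre.  Lead fields map a dipole
moment in A*m to average-referenced electrode potentials in volts.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "HeadModel",
    "ElectrodeMontage",
    "SourceGrid",
    "LeadField",
    "standard_1010_montage",
    "compute_leadfield",
    "homogeneous_sphere_potential",
    "multilayer_potential",
    "make_leadfield_fn",
    "read_montage",
    "write_montage",
    "save_leadfield",
    "load_leadfield",
]

# default shell radii (m), innermost -> outermost, adult-template proportions
DEFAULT_RADII = (0.071, 0.078, 0.081, 0.085, 0.092)
# conductivities (S/m): white matter, gray matter, CSF, skull, scalp
DEFAULT_CONDUCTIVITIES = (0.31, 0.33, 0.33, 0.0042, 0.33)

SERIES_MAX_TERMS = 200


@dataclass(frozen=True)
class HeadModel:
    """Concentric-sphere conductor: radii (m) and conductivities (S/m)."""

    radii: tuple = DEFAULT_RADII
    conductivities: tuple = DEFAULT_CONDUCTIVITIES
    # radial/tangential conductivity ratio of the innermost shell; 1.0 means
    # isotropic (the only regime implemented; kept as an explicit knob)
    anisotropy_ratio: float = 1.0

    def __post_init__(self):
        r = np.asarray(self.radii, float)
        s = np.asarray(self.conductivities, float)
        if r.ndim != 1 or r.size != s.size:
            raise ValueError("radii and conductivities must have equal length")
        if not np.all(np.diff(r) > 0):
            raise ValueError(f"radii must be strictly increasing, got {self.radii}")
        if not np.all(s > 0):
            raise ValueError("conductivities must be strictly positive")
        if self.anisotropy_ratio != 1.0:
            raise NotImplementedError(
                "only isotropic shells are implemented (anisotropy_ratio=1.0)"
            )

    @property
    def inner_radius(self) -> float:
        return float(self.radii[0])

    @property
    def scalp_radius(self) -> float:
        return float(self.radii[-1])


@dataclass(frozen=True)
class ElectrodeMontage:
    """Named electrodes on the scalp sphere.

    Positions are 3-D points (m) lying on the outermost shell surface.
    """

    labels: tuple
    positions: np.ndarray  # (n, 3)

    def __post_init__(self):
        pos = np.asarray(self.positions, float)
        object.__setattr__(self, "positions", pos)
        n = len(self.labels)
        if not 19 <= n <= 128:
            raise ValueError(f"electrode count must be in [19, 128], got {n}")
        if len(set(self.labels)) != n:
            raise ValueError("electrode labels must be unique")
        if pos.shape != (n, 3):
            raise ValueError("positions must be (n_electrodes, 3)")
        radii = np.linalg.norm(pos, axis=1)
        if not np.allclose(radii, radii[0], rtol=1e-6):
            raise ValueError("all electrodes must lie on one sphere surface")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def radius(self) -> float:
        return float(np.linalg.norm(self.positions[0]))

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(",".join(self.labels).encode())
        h.update(np.ascontiguousarray(self.positions).tobytes())
        return h.hexdigest()[:16]


# 10-20 core and its 10-10 extensions, in fixed order so that montages are
# deterministic and nested (each larger set extends the smaller one).
_SUBSET_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)
_EXTRA_32 = ("AF3", "AF4", "FC1", "FC2", "FC5", "FC6", "CP1", "CP2", "CP5",
             "CP6", "PO3", "PO4", "Oz")
_EXTRA_38 = ("Fpz", "FT9", "FT10", "TP9", "TP10", "POz")
_EXTRA_50 = ("F1", "F2", "F5", "F6", "C1", "C2", "C5", "C6", "P1", "P2",
             "P5", "P6")
_EXTRA_64 = ("AF7", "AF8", "AFz", "FT7", "FT8", "FCz", "TP7", "TP8", "CPz",
             "PO7", "PO8", "Iz", "F9", "F10")

_MONTAGE_LABELS = {
    19: _SUBSET_1020,
    32: _SUBSET_1020 + _EXTRA_32,
    38: _SUBSET_1020 + _EXTRA_32 + _EXTRA_38,
    50: _SUBSET_1020 + _EXTRA_32 + _EXTRA_38 + _EXTRA_50,
    64: _SUBSET_1020 + _EXTRA_32 + _EXTRA_38 + _EXTRA_50 + _EXTRA_64,
}


def _fit_sphere_center(points: np.ndarray) -> np.ndarray:
    """Algebraic least-squares sphere fit; returns the centre."""
    p = np.asarray(points, float)
    A = np.hstack([2.0 * p, np.ones((len(p), 1))])
    b = (p ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


def standard_1010_montage(n_electrodes: int = 32,
                          model: HeadModel | None = None) -> ElectrodeMontage:
    """Deterministic 10-10 montage with ``n_electrodes`` channels.

    Electrode directions come from the standard 10-05 position table shipped
    with MNE-Python; positions are projected radially onto the scalp sphere
    of ``model`` (defaults to the template head).
    """
    if n_electrodes not in _MONTAGE_LABELS:
        raise ValueError(
            f"unsupported electrode count {n_electrodes}; "
            f"supported: {sorted(_MONTAGE_LABELS)}"
        )
    model = model or HeadModel()
    labels = _MONTAGE_LABELS[n_electrodes]
    if len(labels) != n_electrodes:  # pragma: no cover - table sanity
        raise RuntimeError("montage label table is inconsistent")
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1005")
    ch_pos = std.get_positions()["ch_pos"]
    raw = np.array([ch_pos[lab] for lab in labels], float)
    center = _fit_sphere_center(raw)
    vec = raw - center
    unit = vec / np.linalg.norm(vec, axis=1, keepdims=True)
    return ElectrodeMontage(labels=labels, positions=unit * model.scalp_radius)


def write_montage(montage: ElectrodeMontage, path) -> None:
    """Write a whitespace-delimited label/x/y/z table (meters)."""
    with open(path, "w") as fh:
        for lab, p in zip(montage.labels, montage.positions):
            fh.write(f"{lab} {p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")


def read_montage(path) -> ElectrodeMontage:
    labels, pos = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            labels.append(parts[0])
            pos.append([float(v) for v in parts[1:4]])
    return ElectrodeMontage(labels=tuple(labels), positions=np.array(pos))


@dataclass(frozen=True)
class SourceGrid:
    """Regular cubic grid of candidate dipole locations inside the brain.

    Nodes are integer multiples of ``voxel_size`` kept strictly inside the
    innermost shell with a one-voxel safety margin.
    """

    voxel_size: float
    nodes: np.ndarray       # (V, 3) coordinates (m)
    ijk: np.ndarray         # (V, 3) signed integer grid indices

    @classmethod
    def for_model(cls, model: HeadModel, voxel_size: float = 0.005) -> "SourceGrid":
        if voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        r_max = model.inner_radius - voxel_size
        k = int(np.floor(r_max / voxel_size))
        ax = np.arange(-k, k + 1)
        ii, jj, kk = np.meshgrid(ax, ax, ax, indexing="ij")
        ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
        nodes = ijk * voxel_size
        keep = np.linalg.norm(nodes, axis=1) <= r_max + 1e-12
        return cls(voxel_size=voxel_size, nodes=nodes[keep], ijk=ijk[keep])

    def __len__(self) -> int:
        return len(self.nodes)

    def nearest_node(self, pos) -> int:
        return int(np.argmin(np.linalg.norm(self.nodes - np.asarray(pos), axis=1)))

    def snap(self, pos) -> np.ndarray:
        """Coordinates of the grid node closest to ``pos``."""
        return self.nodes[self.nearest_node(pos)].copy()


@dataclass
class LeadField:
    """Per-node dipole-to-electrode gain matrices.

    ``matrices[v]`` is (n_electrodes x 3): columns are the average-referenced
    electrode potentials (V) of unit dipoles (1 A*m) along x, y, z at node v.
    """

    grid: SourceGrid
    montage: ElectrodeMontage
    model: HeadModel
    matrices: np.ndarray    # (V, n_elec, 3)
    tol: float

    def __len__(self) -> int:
        return len(self.grid)


# ---------------------------------------------------------------------------
# radial gains through the shell stack
# ---------------------------------------------------------------------------

def _shell_gains(model: HeadModel, n_max: int) -> np.ndarray:
    """Per-degree radial gain g_n, n = 1..n_max.

    g_n generalizes the homogeneous-sphere factor (2n+1)/n: the surface value
    of the degree-n radial solution for a unit source coefficient, with radii
    normalized to the scalp radius.  Interface conditions (continuity of V
    and of sigma * dV/dr) are propagated with 2x2 transfer matrices; the
    outer boundary carries zero radial current.
    """
    radii = np.asarray(model.radii, float) / model.scalp_radius
    sig = np.asarray(model.conductivities, float)
    n = np.arange(1, n_max + 1, dtype=float)
    # accumulate transfer matrix product T(n) over interfaces
    T11 = np.ones_like(n)
    T12 = np.zeros_like(n)
    T21 = np.zeros_like(n)
    T22 = np.ones_like(n)
    for k in range(len(radii) - 1):
        u = radii[k]
        s = sig[k] / sig[k + 1]
        den = 2.0 * n + 1.0
        u_pow = u ** (2.0 * n + 1.0)
        m11 = (n * s + n + 1.0) / den
        m12 = (n + 1.0) * (1.0 - s) / (den * u_pow)
        m21 = n * (1.0 - s) * u_pow / den
        m22 = (n + (n + 1.0) * s) / den
        T11, T12, T21, T22 = (
            m11 * T11 + m12 * T21,
            m11 * T12 + m12 * T22,
            m21 * T11 + m22 * T21,
            m21 * T12 + m22 * T22,
        )
    # zero radial current at u=1: n*A_M = (n+1)*B_M, with (A_M,B_M) = T(x,1)
    denom = n * T11 - (n + 1.0) * T21
    x = ((n + 1.0) * T22 - n * T12) / denom
    a_m = T11 * x + T12
    b_m = T21 * x + T22
    return a_m + b_m


def _series_potentials(positions, moments, elec_unit, model: HeadModel,
                       tol: float = 1e-8) -> np.ndarray:
    """Multilayer series potentials for dipoles at arbitrary interior points.

    Parameters
    ----------
    positions : (V, 3) dipole locations (m)
    moments : (V, 3) or (3,) dipole moments (A*m); broadcast over V
    elec_unit : (E, 3) unit vectors of electrode directions
    tol : relative truncation tolerance of the Legendre series

    Returns
    -------
    (V, E) potentials in volts, not average-referenced.
    """
    if not 0 < tol <= 1e-3:
        raise ValueError("tol must be in (0, 1e-3]")
    pos = np.atleast_2d(np.asarray(positions, float))
    mom = np.broadcast_to(np.asarray(moments, float), pos.shape)
    eu = np.asarray(elec_unit, float)
    R = model.scalp_radius
    r0 = np.linalg.norm(pos, axis=1)
    if np.any(r0 >= model.inner_radius - 1e-6):
        raise ValueError(
            "dipole within 1e-6 m of the innermost shell boundary; "
            "the series solution is not evaluated there"
        )
    b = r0 / R
    u0 = np.where(r0[:, None] > 0, pos / np.maximum(r0, 1e-300)[:, None],
                  np.array([0.0, 0.0, 1.0]))
    gains = _shell_gains(model, SERIES_MAX_TERMS)
    c = u0 @ eu.T                     # (V, E) cos of angular separation
    q_r = np.sum(mom * u0, axis=1)    # (V,) radial moment component
    # tangential projection handled via m . (u_e - c*u0): (V, E)
    m_dot_e = mom @ eu.T
    q_t_term = m_dot_e - c * q_r[:, None]

    # Legendre recurrences, accumulated adaptively
    p_prev = np.ones_like(c)          # P_0
    p_cur = c.copy()                  # P_1
    dp_prev = np.zeros_like(c)        # P_0'
    dp_cur = np.ones_like(c)          # P_1'
    sa = np.zeros_like(c)
    sb = np.zeros_like(c)
    b_pow = np.ones_like(b)           # b^(n-1)
    for n in range(1, SERIES_MAX_TERMS + 1):
        g = gains[n - 1]
        term_a = g * n * b_pow[:, None] * p_cur
        term_b = g * b_pow[:, None] * dp_cur
        sa += term_a
        sb += term_b
        scale = max(np.max(np.abs(sa)), np.max(np.abs(sb)), 1e-300)
        change = max(np.max(np.abs(term_a)), np.max(np.abs(term_b)))
        if n >= 2 and change <= tol * scale:
            break
        # advance recurrences to degree n+1
        p_next = ((2 * n + 1) * c * p_cur - n * p_prev) / (n + 1)
        dp_next = dp_prev + (2 * n + 1) * p_cur
        p_prev, p_cur = p_cur, p_next
        dp_prev, dp_cur = dp_cur, dp_next
        b_pow = b_pow * b
    pref = 1.0 / (4.0 * np.pi * model.conductivities[0] * R ** 2)
    return pref * (q_r[:, None] * sa + q_t_term * sb)


def multilayer_potential(dipole_pos, dipole_moment, electrode_pos,
                         model: HeadModel | None = None,
                         tol: float = 1e-8) -> np.ndarray:
    """Scalp potentials (V) of one dipole in the multilayer sphere model.

    ``electrode_pos`` are points on the scalp surface; the output is *not*
    average-referenced (single-dipole potentials relative to infinity).
    """
    model = model or HeadModel()
    ep = np.atleast_2d(np.asarray(electrode_pos, float))
    radii = np.linalg.norm(ep, axis=1)
    if not np.allclose(radii, model.scalp_radius, rtol=1e-6):
        raise ValueError("electrodes must lie on the scalp sphere surface")
    eu = ep / radii[:, None]
    out = _series_potentials(dipole_pos, dipole_moment, eu, model, tol)
    return out[0]


def homogeneous_sphere_potential(dipole_pos, dipole_moment, electrode_pos,
                                 radius: float, conductivity: float) -> np.ndarray:
    """Closed-form surface potential of a dipole in a homogeneous sphere.

    Obtained by summing the Legendre expansion in closed form (generating
    functions), independent of the multilayer transfer-matrix solver; serves
    as its oracle when all conductivities are equal.
    """
    pos = np.asarray(dipole_pos, float)
    mom = np.asarray(dipole_moment, float)
    ep = np.atleast_2d(np.asarray(electrode_pos, float))
    r0 = float(np.linalg.norm(pos))
    if r0 >= radius * (1.0 - 1e-9):
        raise ValueError("dipole must be strictly inside the sphere")
    if not np.allclose(np.linalg.norm(ep, axis=1), radius, rtol=1e-6):
        raise ValueError("electrodes must lie on the sphere surface")
    eu = ep / np.linalg.norm(ep, axis=1, keepdims=True)
    pref = 1.0 / (4.0 * np.pi * conductivity * radius ** 2)
    if r0 < 1e-12 * radius:
        # central dipole: only the n=1 term survives
        return pref * 3.0 * (eu @ mom)
    u0 = pos / r0
    b = r0 / radius
    cg = eu @ u0
    q_r = float(mom @ u0)
    q_t_term = eu @ mom - cg * q_r
    f = np.sqrt(1.0 - 2.0 * b * cg + b * b)   # |electrode - dipole| / radius
    s1 = 2.0 * (cg - b) / f ** 3 + (1.0 / f - 1.0) / b
    s2_over_sin = 2.0 / f ** 3 + (f + 1.0) / (f * (1.0 - cg * b + f))
    return pref * (q_r * s1 + q_t_term * s2_over_sin)


def compute_leadfield(grid: SourceGrid, montage: ElectrodeMontage,
                      model: HeadModel | None = None,
                      tol: float = 1e-8,
                      chunk: int = 2048) -> LeadField:
    """Lead-field matrices for every grid node.

    For each node the three columns are the average-referenced electrode
    potentials of unit dipoles along x, y, z, with the Legendre series
    truncated adaptively at relative tolerance ``tol``.
    """
    model = model or HeadModel()
    if not np.allclose(np.linalg.norm(montage.positions, axis=1),
                       model.scalp_radius, rtol=1e-6):
        raise ValueError("montage does not lie on this model's scalp sphere")
    eu = montage.positions / np.linalg.norm(montage.positions, axis=1,
                                            keepdims=True)
    V, E = len(grid), len(montage)
    L = np.empty((V, E, 3))
    eye = np.eye(3)
    for lo in range(0, V, chunk):
        hi = min(lo + chunk, V)
        for a in range(3):
            L[lo:hi, :, a] = _series_potentials(
                grid.nodes[lo:hi], eye[a], eu, model, tol)
    L -= L.mean(axis=1, keepdims=True)   # average reference
    if not np.all(np.isfinite(L)):
        raise FloatingPointError("non-finite lead-field values")
    return LeadField(grid=grid, montage=montage, model=model,
                     matrices=L, tol=tol)


def make_leadfield_fn(montage: ElectrodeMontage,
                      model: HeadModel | None = None, tol: float = 1e-8):
    """Forward-model evaluator at arbitrary interior positions.

    Returns ``fn(pos, moment) -> (n_electrodes,)`` average-referenced
    potentials (V) for a dipole moment in A*m.
    """
    model = model or HeadModel()
    eu = montage.positions / np.linalg.norm(montage.positions, axis=1,
                                            keepdims=True)

    def fn(pos, moment):
        v = _series_potentials(pos, moment, eu, model, tol)[0]
        return v - v.mean()

    return fn


# ---------------------------------------------------------------------------
# lead-field persistence (runtime cache)
# ---------------------------------------------------------------------------

def _model_dict(model: HeadModel) -> dict:
    return {"radii": list(model.radii),
            "conductivities": list(model.conductivities)}


def save_leadfield(lf: LeadField, path) -> None:
    """Persist a lead field as .npz plus a JSON provenance header."""
    path = Path(path)
    np.savez_compressed(path, matrices=lf.matrices, nodes=lf.grid.nodes,
                        ijk=lf.grid.ijk,
                        positions=lf.montage.positions)
    header = {
        "model": _model_dict(lf.model),
        "montage_hash": lf.montage.content_hash(),
        "labels": list(lf.montage.labels),
        "voxel_size": lf.grid.voxel_size,
        "tol": lf.tol,
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))


def load_leadfield(path) -> LeadField:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    header = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path)
    model = HeadModel(radii=tuple(header["model"]["radii"]),
                      conductivities=tuple(header["model"]["conductivities"]))
    montage = ElectrodeMontage(labels=tuple(header["labels"]),
                               positions=data["positions"])
    grid = SourceGrid(voxel_size=header["voxel_size"], nodes=data["nodes"],
                      ijk=data["ijk"])
    return LeadField(grid=grid, montage=montage, model=model,
                     matrices=data["matrices"], tol=header["tol"])
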