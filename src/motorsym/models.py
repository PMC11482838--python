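"""Pseudo-atomic models: Gaussian blobs with protomer labels.

A :class:`PseudoAtomModel` stands in for an atomic model wherever one is
rasterized into density, bent onto a ring, or scored against a map.  Each
"atom" is an isotropic 3-D Gaussian with a peak amplitude and width sigma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import gemmi

from .volume import Volume


@dataclass
class ProtomerShape:
    """Building-block shape: a handful of Gaussian blobs in the protomer frame.

    ``blobs`` is a list of ``(offset_xyz_Å, amplitude, sigma_Å)``.  The
    default fixture is an asymmetric "L" so that azimuthal phase and
    handedness remain detectable after ring assembly.
    """

    blobs: list[tuple[tuple[float, float, float], float, float]]
    label: str = "protomer"

    def __post_init__(self) -> None:
        if len(self.blobs) == 0:
            raise ValueError("ProtomerShape needs at least one blob")
        for off, amp, sig in self.blobs:
            if not np.all(np.isfinite(off)):
                raise ValueError("blob offset must be finite")
            if not (sig > 0):
                raise ValueError(f"blob sigma must be > 0, got {sig}")


def default_protomer(label: str = "protomer", scale: float = 1.0) -> ProtomerShape:
    """L-shaped three-blob fixture; offsets in Å, unit peak amplitude."""
    s = scale
    return ProtomerShape(
        blobs=[
            ((0.0, 0.0, 0.0), 1.0, 3.0 * s),
            ((5.0 * s, 0.0, 0.0), 0.8, 2.5 * s),
            ((0.0, 0.0, 6.0 * s), 0.6, 2.5 * s),
        ],
        label=label,
    )


def post_protomer(label: str = "post") -> ProtomerShape:
    """Vertical two-blob post, emulating C-ring protomer architecture."""
    return ProtomerShape(
        blobs=[((0.0, 0.0, 0.0), 1.0, 3.0), ((0.0, 0.0, 8.0), 1.0, 3.0)],
        label=label,
    )


@dataclass
class PseudoAtomModel:
    """A set of Gaussian blobs with per-blob chain labels.

    positions : (N, 3) Å, box-centre-relative
    amplitudes, sigmas : (N,)
    chains : length-N list of chain labels (one chain per protomer)
    """

    positions: np.ndarray
    amplitudes: np.ndarray
    sigmas: np.ndarray
    chains: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        self.sigmas = np.atleast_1d(np.asarray(self.sigmas, dtype=float))
        n = len(self.positions)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (N, 3)")
        if len(self.amplitudes) != n or len(self.sigmas) != n:
            raise ValueError("amplitudes/sigmas must match positions")
        if n == 0:
            raise ValueError("model must contain at least one blob")
        if not self.chains:
            self.chains = ["A"] * n
        if np.any(self.sigmas <= 0):
            raise ValueError("all sigmas must be > 0")

    def __len__(self) -> int:
        return len(self.positions)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PseudoAtomModel":
        """Rigid transform: positions -> R @ p + t."""
        return PseudoAtomModel(
            self.positions @ np.asarray(rotation).T + np.asarray(translation),
            self.amplitudes.copy(),
            self.sigmas.copy(),
            list(self.chains),
        )

    @staticmethod
    def concatenate(parts: list["PseudoAtomModel"]) -> "PseudoAtomModel":
        return PseudoAtomModel(
            np.vstack([p.positions for p in parts]),
            np.concatenate([p.amplitudes for p in parts]),
            np.concatenate([p.sigmas for p in parts]),
            [c for p in parts for c in p.chains],
        )

    @staticmethod
    def from_protomer(shape: ProtomerShape, chain: str = "A") -> "PseudoAtomModel":
        offs = np.array([b[0] for b in shape.blobs], dtype=float)
        amps = np.array([b[1] for b in shape.blobs], dtype=float)
        sigs = np.array([b[2] for b in shape.blobs], dtype=float)
        return PseudoAtomModel(offs, amps, sigs, [chain] * len(offs))

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def max_radius(self) -> float:
        """Largest cylindrical radius of any blob centre plus 4 sigma, Å."""
        r = np.hypot(self.positions[:, 0], self.positions[:, 1])
        return float(np.max(r + 4.0 * self.sigmas))

    def to_pdb(self, path: str) -> None:
        """Export as a pseudo-atom PDB file, one chain per protomer label."""
        st = gemmi.Structure()
        st.name = "pseudo-atom ring model"
        model = gemmi.Model("1")
        chain_map: dict[str, gemmi.Chain] = {}
        for i, (pos, amp, sig, ch) in enumerate(
            zip(self.positions, self.amplitudes, self.sigmas, self.chains)
        ):
            if ch not in chain_map:
                chain_map[ch] = gemmi.Chain(_chain_id(len(chain_map)))
            chain = chain_map[ch]
            res = gemmi.Residue()
            res.name = "BLB"
            res.seqid = gemmi.SeqId(len(chain) + 1, " ")
            atom = gemmi.Atom()
            atom.name = "C"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*pos)
            atom.occ = float(amp)
            atom.b_iso = float(sig)
            res.add_atom(atom)
            chain.add_residue(res)
        for chain in chain_map.values():
            model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        st.write_pdb(path)


def _chain_id(k: int) -> str:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    return alphabet[k % len(alphabet)]


def rasterize(model: PseudoAtomModel, box_size: int, voxel_size: float) -> Volume:
    """Rasterize a pseudo-atom model into a density volume.

    Each blob contributes ``amp * exp(-d^2 / 2 sigma^2)`` evaluated within
    6 sigma of its centre (tail truncation < 2e-8 of the peak).  Blobs whose
    centre falls outside the box are skipped with a warning reporting the
    truncation count.
    """
    n = int(box_size)
    if n % 2 != 0 or n < 2:
        raise ValueError(f"box_size must be even and >= 2, got {box_size}")
    grid = np.zeros((n, n, n))
    c = n / 2.0
    axis = (np.arange(n) - c) * voxel_size
    truncated = 0
    for pos, amp, sig in zip(model.positions, model.amplitudes, model.sigmas):
        vc = pos / voxel_size + c
        if np.any(vc < 0) or np.any(vc >= n):
            truncated += 1
            continue
        half = 6.0 * sig / voxel_size
        lo = np.maximum(np.floor(vc - half).astype(int), 0)
        hi = np.minimum(np.ceil(vc + half).astype(int) + 1, n)
        dx = axis[lo[0]:hi[0]] - pos[0]
        dy = axis[lo[1]:hi[1]] - pos[1]
        dz = axis[lo[2]:hi[2]] - pos[2]
        d2 = (
            dx[:, None, None] ** 2
            + dy[None, :, None] ** 2
            + dz[None, None, :] ** 2
        )
        grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amp * np.exp(
            -d2 / (2.0 * sig**2)
        )
    if truncated:
        warnings.warn(
            f"{truncated} blob(s) outside the box were truncated", stacklevel=2
        )
    return Volume(grid, voxel_size)
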