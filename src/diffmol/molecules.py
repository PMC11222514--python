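"""Molecule records and their mapping to and from the diffusion latent space.

A molecule is element symbols, integer formal charges, and Cartesian
coordinates in angstroms.  Featurisation packs types and charges into the
invariant channel z^(h) — one-hot type block scaled by 0.25 and a charge slot
scaled by 0.1, the relative scaling that balances the two integer-valued
feature families against unit-variance noise — and centres the coordinates on
the zero-CoG subspace.  Decoding inverts this with argmax types and
round-half-away-from-zero charges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diffusion import LatentState, project_zero_cog

__all__ = [
    "MoleculeRecord",
    "QM9_ALPHABET",
    "fully_connected_edges",
    "featurize",
    "decode_latent",
]

#: atom types of small drug-like organics at QM9 scale
QM9_ALPHABET: tuple[str, ...] = ("H", "C", "N", "O", "F")

ONEHOT_SCALE = 0.25
CHARGE_SCALE = 0.1


@dataclass
class MoleculeRecord:
    """A decoded 3D molecule: types, charges and coordinates (angstrom)."""

    elements: list[str]
    coords: np.ndarray
    charges: np.ndarray | None = None
    properties: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        n = len(self.elements)
        if n < 1:
            raise ValueError("a molecule needs at least one atom")
        if self.coords.shape[0] != n:
            raise ValueError(
                f"{n} elements but {self.coords.shape[0]} coordinate rows"
            )
        if self.charges is None:
            self.charges = np.zeros(n, dtype=np.int64)
        else:
            self.charges = np.asarray(self.charges, dtype=np.int64).reshape(n)

    @property
    def N(self) -> int:
        return len(self.elements)

    def pairwise_distances(self) -> np.ndarray:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((d**2).sum(-1))


def fully_connected_edges(N: int) -> np.ndarray:
    """All ordered pairs (i, j), i != j, as an (E, 2) integer array."""
    idx = np.arange(N)
    send, recv = np.meshgrid(idx, idx, indexing="ij")
    mask = send != recv
    return np.stack([send[mask], recv[mask]], axis=1)


def featurize(
    mol: MoleculeRecord,
    alphabet=QM9_ALPHABET,
    onehot_scale: float = ONEHOT_SCALE,
    charge_scale: float = CHARGE_SCALE,
) -> tuple[LatentState, np.ndarray]:
    """Encode a molecule as a clean latent state plus its edge skeleton.

    Returns the t = 0 LatentState (centred coordinates, scaled one-hot +
    charge features) and the directed fully-connected edge list.
    """
    alphabet = tuple(alphabet)
    index = {el: k for k, el in enumerate(alphabet)}
    try:
        type_idx = np.array([index[el] for el in mol.elements])
    except KeyError as err:
        raise ValueError(f"element {err} outside alphabet {alphabet}") from None
    onehot = np.zeros((mol.N, len(alphabet)))
    onehot[np.arange(mol.N), type_idx] = 1.0
    zh = np.concatenate(
        [onehot * onehot_scale, mol.charges[:, None] * charge_scale], axis=1
    )
    zx = project_zero_cog(mol.coords)
    return LatentState(zx=zx, zh=zh, t=0), fully_connected_edges(mol.N)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def decode_latent(
    z0: LatentState,
    alphabet=QM9_ALPHABET,
    onehot_scale: float = ONEHOT_SCALE,
    charge_scale: float = CHARGE_SCALE,
) -> MoleculeRecord:
    """Decode a clean latent state back into a molecule record.

    Element = argmax of the unscaled one-hot block; charge = nearest integer
    of the unscaled charge slot (ties round away from zero); coordinates pass
    through unchanged.
    """
    alphabet = tuple(alphabet)
    n_types = len(alphabet)
    onehot = z0.zh[:, :n_types] / onehot_scale
    type_idx = onehot.argmax(axis=1)
    charges = _round_half_away(z0.zh[:, n_types] / charge_scale).astype(np.int64)
    return MoleculeRecord(
        elements=[alphabet[k] for k in type_idx],
        coords=z0.zx.copy(),
        charges=charges,
    )
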