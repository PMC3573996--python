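"""Monte Carlo van der Waals molecular volume.

The molecule is embedded in the axis-aligned box just enclosing all atom
spheres; uniform points are drawn in the box and V_mol is estimated as

    V_mol = V_box * N_hits / N_trials

with the binomial standard error V_box * sqrt(p(1-p)/N_trials).  The box is
axis-aligned in the input frame; the estimator is unbiased for any
enclosing box, so orientation affects only the variance.  Boundary points
count as hits (closed spheres) — a measure-zero convention fixed for
determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from solvcontact.mol import Molecule

# van der Waals radii, A
DEFAULT_RADII: dict[str, float] = {
    "C": 1.53, "N": 1.45, "O": 1.36, "S": 1.70, "H": 1.08,
    "F": 1.30, "Cl": 1.65, "Br": 1.80, "I": 2.05,
}


@dataclass
class VolumeEstimate:
    V_mol: float      # A^3
    V_box: float      # A^3
    N_trials: int
    N_hits: int
    std_error: float  # A^3
    seed: int | None


def _radii_vector(mol: Molecule, radii: dict[str, float]) -> np.ndarray:
    missing = sorted({a.element for a in mol.atoms} - set(radii))
    if missing:
        raise ValueError(
            f"no van der Waals radius for element(s) {missing}; "
            "supply an explicit radius override")
    return np.array([radii[a.element] for a in mol.atoms])


def bounding_box(mol: Molecule, radii: dict[str, float] | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned box (min corner, max corner) enclosing every atom sphere."""
    if mol.n_atoms == 0:
        raise ValueError("cannot box an empty molecule")
    r = _radii_vector(mol, DEFAULT_RADII if radii is None else radii)
    return _tight_box(mol.coords, r)


def _tight_box(coords: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return (coords - r[:, None]).min(axis=0), (coords + r[:, None]).max(axis=0)


def point_in_vdw(mol: Molecule, radii: dict[str, float] | None, point) -> bool:
    """True iff the point lies within (or on) any atom's van der Waals sphere."""
    if mol.n_atoms == 0:
        return False
    r = _radii_vector(mol, DEFAULT_RADII if radii is None else radii)
    d2 = np.sum((mol.coords - np.asarray(point, dtype=float)) ** 2, axis=1)
    return bool(np.any(d2 <= r ** 2))


def mc_volume(mol: Molecule, radii: dict[str, float] | None = None,
              n_trials: int = 1_000_000, seed: int | None = None,
              batch: int = 262_144) -> VolumeEstimate:
    """Monte Carlo estimate of the union-of-spheres volume.

    Reproducible: the same seed yields a bitwise-identical estimate.  The
    standard error is always reported so callers can judge convergence;
    the default 10^6 trials gives a relative error well under 1% for
    drug-sized molecules.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    r = _radii_vector(mol, DEFAULT_RADII if radii is None else radii)
    if mol.n_atoms == 0:
        raise ValueError("cannot estimate the volume of an empty molecule")
    coords = mol.coords
    lo, hi = _tight_box(coords, r)
    v_box = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    r2 = r ** 2
    hits = 0
    done = 0
    while done < n_trials:
        m = min(batch, n_trials - done)
        pts = rng.uniform(lo, hi, size=(m, 3))
        d2 = np.sum((pts[:, None, :] - coords[None, :, :]) ** 2, axis=2)
        hits += int(np.any(d2 <= r2[None, :], axis=1).sum())
        done += m
    p_hat = hits / n_trials
    v_mol = v_box * p_hat
    se = v_box * float(np.sqrt(p_hat * (1.0 - p_hat) / n_trials))
    return VolumeEstimate(V_mol=v_mol, V_box=v_box, N_trials=n_trials,
                          N_hits=hits, std_error=se, seed=seed)
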