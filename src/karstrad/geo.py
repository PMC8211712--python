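"""Ancestral geographic reconstruction by Brownian motion on the sphere.

Longitude/latitude are embedded as unit vectors in 3-D Cartesian space and
each axis is treated as an independent Brownian trait on the chronogram,
which avoids the distortions a raw lon/lat parameterisation suffers near
the poles and the date line.  Ancestral locations at nodes, or at fixed
time slices along branches, are sampled from the exact conditional
Gaussian given the tips (the Brownian posterior is Gaussian, so no MCMC is
needed), renormalised back to the sphere, and summarised by a centroid
with a 95% centroid-trimmed credible region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .tree import TimeTree, TreeError

__all__ = [
    "to_cartesian",
    "from_cartesian",
    "GeoBrownianModel",
    "GeoReconstruction",
    "credible_region",
]


def to_cartesian(lon: float, lat: float) -> np.ndarray:
    """(lon, lat) in decimal degrees -> unit 3-vector."""
    if not (-180.0 <= lon <= 180.0) or not (-90.0 <= lat <= 90.0):
        raise ValueError(f"coordinates out of range: lon={lon}, lat={lat}")
    lo, la = np.deg2rad(lon), np.deg2rad(lat)
    return np.array([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)])


def from_cartesian(v: Sequence[float]) -> Tuple[float, float]:
    """Unit(ish) 3-vector -> (lon, lat) in decimal degrees (renormalises)."""
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValueError("zero vector has no direction")
    v = v / norm
    lat = np.rad2deg(np.arcsin(np.clip(v[2], -1, 1)))
    lon = np.rad2deg(np.arctan2(v[1], v[0]))
    return float(lon), float(lat)


@dataclass
class GeoReconstruction:
    """Posterior location samples for one target (node or time slice)."""

    target: object
    samples_xyz: np.ndarray  # (n_draws, 3), on the unit sphere
    centroid_xyz: np.ndarray
    retained: np.ndarray  # indices of the 95% retained samples

    @property
    def centroid_lonlat(self) -> Tuple[float, float]:
        return from_cartesian(self.centroid_xyz)

    def samples_lonlat(self) -> np.ndarray:
        return np.array([from_cartesian(v) for v in self.samples_xyz])

    def retained_lonlat(self) -> np.ndarray:
        return np.array([from_cartesian(v) for v in self.samples_xyz[self.retained]])


def credible_region(samples_xyz: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Centroid (normalised mean vector) and 95% centroid-trimmed set.

    Distances are angular (great-circle); the 5% of samples farthest from
    the centroid are discarded.  Returns (retained indices, centroid).
    """
    X = np.asarray(samples_xyz, dtype=float)
    if len(X) < 20:
        raise ValueError("need at least 20 samples for a 95% region")
    m = X.mean(axis=0)
    if np.linalg.norm(m) < 1e-6:
        raise ValueError("centroid undefined: samples antipodally balanced")
    c = m / np.linalg.norm(m)
    ang = np.arccos(np.clip(X @ c, -1.0, 1.0))
    n_keep = int(np.ceil(0.95 * len(X)))
    retained = np.argsort(ang, kind="stable")[:n_keep]
    return np.sort(retained), c


class GeoBrownianModel:
    """Brownian motion on sphere-embedded coordinates of the tips.

    Parameters
    ----------
    tree : TimeTree
    coordinates : DataFrame with columns lon, lat indexed by tip label
        (tips without coordinates are pruned from the tree).
    """

    def __init__(self, tree: TimeTree, coordinates: pd.DataFrame):
        coords = coordinates.dropna()
        tips = sorted(set(tree.tip_labels) & set(coords.index))
        if len(tips) < 3:
            raise ValueError("need >= 3 tips with coordinates")
        self.tree = tree.prune_to(tips) if len(tips) < tree.n_tips else tree
        self.tips = self.tree.tip_labels
        self.X = np.array([to_cartesian(*coords.loc[t, ["lon", "lat"]]) for t in self.tips])
        _, self.C = self.tree.vcv(self.tips)
        self._chol = np.linalg.cholesky(self.C + 1e-12 * np.eye(len(self.tips)))

    # -- helpers -------------------------------------------------------
    def _gls_mean(self) -> np.ndarray:
        ones = np.ones(len(self.tips))
        Ci1 = np.linalg.solve(self.C, ones)
        denom = ones @ Ci1
        return (self.X.T @ Ci1) / denom

    def reml_rate(self) -> float:
        """Per-axis Brownian rate via REML on independent contrasts,
        pooled across the three Cartesian axes."""
        from .traitgeom import contrasts

        rates = []
        for j in range(3):
            y = pd.Series(self.X[:, j], index=self.tips)
            pic = contrasts(self.tree, y)
            rates.append(float(np.mean(pic.contrast**2)))
        return float(np.mean(rates))

    def _target_cov(self, targets) -> Tuple[np.ndarray, np.ndarray]:
        """Shared-path covariances target-vs-tip and target-vs-target.

        A target is either a node (given as a frozenset/iterable of tip
        labels whose MRCA it is) or ("slice", tipset, age): the point on
        the branch ancestral to MRCA(tipset) at the given age.
        """
        T = self.tree.crown_age
        n = len(self.tips)
        pos = {t: i for i, t in enumerate(self.tips)}
        A = np.zeros((len(targets), n))
        B = np.zeros((len(targets), len(targets)))
        anc_paths = []  # list of (node, age) describing each target point
        for t in targets:
            if isinstance(t, tuple) and t and t[0] == "slice":
                _, tipset, age = t
                node = self.tree.mrca(set(tipset) & set(self.tips))
                # walk rootward until the branch spans the requested age
                while node.parent_node is not None and node.parent_node.age_my < age:
                    node = node.parent_node
                if age > T:
                    raise TreeError(f"slice age {age} older than crown {T}")
                if node.parent_node is None and age > T:
                    raise TreeError("age above root")
                anc_paths.append((node, float(age)))
            else:
                node = self.tree.mrca(set(t) & set(self.tips))
                anc_paths.append((node, node.age_my))
        for i, (node, age) in enumerate(anc_paths):
            desc = self.tree.tipset(node)
            for tip in self.tips:
                if tip in desc:
                    A[i, pos[tip]] = T - age
                else:
                    # shared path = root-to-MRCA(tip, node)
                    mrca = self.tree.mrca(desc | {tip})
                    A[i, pos[tip]] = T - mrca.age_my
            for j, (node2, age2) in enumerate(anc_paths[: i + 1]):
                desc2 = self.tree.tipset(node2)
                if desc <= desc2 or desc2 <= desc:
                    B[i, j] = B[j, i] = T - max(age, age2)
                else:
                    mrca = self.tree.mrca(desc | desc2)
                    B[i, j] = B[j, i] = T - mrca.age_my
        return A, B

    # -- main API ------------------------------------------------------
    def reconstruct(
        self,
        targets: Sequence[object],
        n_draws: int = 1000,
        seed=None,
    ) -> List[GeoReconstruction]:
        """Sample ancestral locations for each target.

        Targets are tip-label collections (the node is their MRCA) or
        ``("slice", tipset, age)`` for a point along the stem lineage of a
        clade at a fixed age.
        """
        rng = np.random.default_rng(seed)
        sigma2 = self.reml_rate()
        mu = self._gls_mean()
        A, B = self._target_cov(targets)
        n = len(self.tips)
        Cinv_list = []
        # conditional Gaussian per axis: mean_t = mu + A C^-1 (x - mu),
        # cov_t = sigma2 * (B - A C^-1 A')
        CinvAt = np.linalg.solve(self.C, A.T)
        condcov = sigma2 * (B - A @ CinvAt)
        condcov = (condcov + condcov.T) / 2
        w, V = np.linalg.eigh(condcov)
        w = np.clip(w, 0, None)
        Lc = V @ np.diag(np.sqrt(w))
        out = []
        means = np.empty((len(targets), 3))
        for ax in range(3):
            resid = self.X[:, ax] - mu[ax]
            means[:, ax] = mu[ax] + CinvAt.T @ resid
        draws = np.empty((n_draws, len(targets), 3))
        for ax in range(3):
            z = rng.standard_normal((n_draws, len(targets)))
            draws[:, :, ax] = means[:, ax] + z @ Lc.T
        for i, t in enumerate(targets):
            S = draws[:, i, :]
            S = S / np.linalg.norm(S, axis=1, keepdims=True)
            retained, c = credible_region(S) if n_draws >= 20 else (np.arange(n_draws), S.mean(0) / np.linalg.norm(S.mean(0)))
            out.append(GeoReconstruction(t, S, c, retained))
        return out

    def conditional_mean_root(self) -> np.ndarray:
        """Conditional mean at the root (= GLS phylogenetic mean)."""
        return self._gls_mean()
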