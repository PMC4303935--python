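"""Barycentric (ternary) coordinates for three-center distance profiles.

With exactly three centers a sample's profile (r1, r2, r3) can be placed
inside an equilateral triangle.  Two conventions coexist:

* ``d``:  d_i = r_i / (r1 + r2 + r3) — directly proportional to the
  distance from center i, so a sample sitting ON center j has d_j = 0.
* ``D``:  D_i = (1 − d_i) / 2 — the ternary-mixture convention used by
  most plotting packages, where a large coordinate means proximity to
  vertex i; a sample on center j has the maximal D_j (= 1/2).

Both triples are non-negative and sum to one, and the conversion is an
invertible affine map, so nothing is lost either way.  ``D`` is the
default for plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateDataError
from .io import FLOAT_FORMAT, SampleMetadata

#: vertices of the unit equilateral triangle used for embedding
TRIANGLE_VERTICES = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, math.sqrt(3.0) / 2.0]])


@dataclass(frozen=True)
class BarycentricPoint:
    """Normalized coordinates of one sample in a three-center triangle."""

    d: np.ndarray
    D: np.ndarray
    vertex_labels: tuple[str, str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float))
        object.__setattr__(self, "D", np.asarray(self.D, dtype=float))
        for name, c in (("d", self.d), ("D", self.D)):
            if c.shape != (3,):
                raise ConfigurationError(f"{name} must have exactly 3 coordinates")
            if (c < -1e-12).any() or abs(c.sum() - 1.0) > 1e-12:
                raise DegenerateDataError(
                    f"{name} coordinates must be non-negative and sum to 1; got {c}"
                )


def distance_to_plot(d: np.ndarray) -> np.ndarray:
    """Convert distance-proportional coordinates to the plot convention.

    D_i = (1/2) (1 − d_i / Σ_j d_j); for an already-normalized d this is
    (1 − d_i) / 2, the unique affine image with ΣD = 1.
    """
    d = np.asarray(d, dtype=float)
    tot = d.sum()
    if tot <= 0:
        raise DegenerateDataError("cannot convert all-zero coordinates")
    return 0.5 * (1.0 - d / tot)


def plot_to_distance(D: np.ndarray) -> np.ndarray:
    """Inverse of :func:`distance_to_plot` for normalized triples."""
    D = np.asarray(D, dtype=float)
    return 1.0 - 2.0 * D


def to_barycentric(r, vertex_labels=None) -> BarycentricPoint:
    """Barycentric point of a three-center distance profile.

    ``r`` may be a length-3 sequence or a pandas Series whose index
    supplies the vertex labels.  Requires a strictly positive total
    distance.
    """
    if isinstance(r, pd.Series):
        vertex_labels = tuple(r.index) if vertex_labels is None else tuple(vertex_labels)
        r = r.to_numpy(dtype=float)
    r = np.asarray(r, dtype=float)
    if r.shape != (3,):
        raise ConfigurationError(
            f"barycentric coordinates need exactly 3 distances, got {r.shape}"
        )
    if (r < 0).any():
        raise DegenerateDataError("distances must be non-negative")
    tot = r.sum()
    if tot == 0:
        raise DegenerateDataError(
            "degenerate profile: all three distances are zero"
        )
    if vertex_labels is None:
        vertex_labels = ("v1", "v2", "v3")
    d = r / tot
    return BarycentricPoint(d=d, D=distance_to_plot(d),
                            vertex_labels=tuple(vertex_labels))


def ternary_to_cartesian(point, convention: str = "D") -> np.ndarray:
    """Planar embedding of a barycentric point in the unit equilateral
    triangle with vertices (0,0), (1,0), (1/2, √3/2).

    ``point`` may be a BarycentricPoint (``convention`` selects which
    triple to embed) or a raw normalized triple.
    """
    if isinstance(point, BarycentricPoint):
        if convention == "d":
            c = point.d
        elif convention == "D":
            c = point.D
        else:
            raise ConfigurationError(f"unknown convention {convention!r}")
    else:
        c = np.asarray(point, dtype=float)
        if c.shape != (3,):
            raise ConfigurationError("need a triple of coordinates")
    return c @ TRIANGLE_VERTICES


def barycentric_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Both coordinate triples for every row of a 3-center profile table."""
    if profiles.shape[1] != 3:
        raise ConfigurationError(
            f"barycentric table needs exactly 3 centers, got {profiles.shape[1]}"
        )
    labels = tuple(profiles.columns)
    rows = {}
    for sid in profiles.index:
        p = to_barycentric(profiles.loc[sid])
        rows[sid] = np.concatenate([p.d, p.D])
    cols = [f"d_{l}" for l in labels] + [f"D_{l}" for l in labels]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols).rename_axis(
        "sample_id"
    )


def write_barycentric(
    profiles: pd.DataFrame,
    metadata: SampleMetadata,
    path: str | Path,
) -> None:
    """Tab-separated table of d and D coordinates, vertex labels in the header."""
    tab = barycentric_table(profiles)
    tab.insert(0, "group", metadata.groups.reindex(tab.index))
    tab.to_csv(Path(path), sep="\t", index_label="sample_id",
               float_format=FLOAT_FORMAT)
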