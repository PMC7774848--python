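"""Airfoil section geometry: NACA 4-digit-law generation and Selig file I/O.

Shapes are stored in chord units as a single coordinate loop in Selig order
(trailing edge -> upper surface -> leading edge -> lower surface -> trailing
edge), with the chord on the x-axis from 0 (leading edge) to 1 (trailing edge)
and the suction side at +y.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["AirfoilShape", "AirfoilFileError", "naca4_coordinates", "read_airfoil_dat", "write_airfoil_dat"]


class AirfoilFileError(ValueError):
    """Raised for an unreadable or malformed airfoil coordinate file."""


@dataclass(frozen=True)
class AirfoilShape:
    """Closed 2-D section contour in chord units, Selig node order."""

    name: str
    coords: np.ndarray  # (n, 2)
    closed_te: bool = True

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 10:
            raise ValueError("shape needs at least 10 (x, y) coordinate pairs")
        span = c[:, 0].max() - c[:, 0].min()
        if not 0.98 < span < 1.02:
            raise ValueError(f"chord not normalized to 1 (extent {span:.4f})")

    @property
    def n_points(self) -> int:
        return len(self.coords)

    def thickness(self) -> float:
        """Maximum thickness/chord, from upper/lower interpolation on a fine grid."""
        xu, yu, xl, yl = self._split_surfaces()
        xs = np.linspace(0.005, 0.995, 400)
        t = np.interp(xs, xu, yu) - np.interp(xs, xl, yl)
        return float(t.max())

    def _split_surfaces(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        c = self.coords
        i_le = int(np.argmin(c[:, 0]))
        upper = c[: i_le + 1][::-1]  # LE -> TE
        lower = c[i_le:]
        return upper[:, 0], upper[:, 1], lower[:, 0], lower[:, 1]


def naca4_coordinates(
    thickness: float,
    camber: float = 0.0,
    camber_pos: float = 0.4,
    n_points: int = 201,
    closed_te: bool = True,
    name: str | None = None,
) -> AirfoilShape:
    """NACA 4-digit thickness/camber laws with cosine point spacing.

    ``thickness``, ``camber`` and ``camber_pos`` are fractions of chord.
    ``n_points`` is the total number of loop nodes (odd counts put a node
    exactly at the leading edge).  ``closed_te`` rescales the last thickness
    coefficient so the trailing edge closes to a sharp point.
    """
    if not 0 < thickness < 0.4:
        raise ValueError(f"thickness must lie in (0, 0.4), got {thickness}")
    if not 0 <= camber < 0.1:
        raise ValueError(f"camber must lie in [0, 0.1), got {camber}")
    if camber > 0 and not 0.1 <= camber_pos <= 0.9:
        raise ValueError(f"camber position must lie in [0.1, 0.9], got {camber_pos}")
    if n_points < 40:
        raise ValueError(f"need at least 40 points, got {n_points}")

    n_side = n_points // 2 + 1
    beta = np.linspace(0.0, np.pi, n_side)
    x = 0.5 * (1.0 - np.cos(beta))  # cosine clustering at LE and TE

    a4 = -0.1036 if closed_te else -0.1015
    yt = 5.0 * thickness * (
        0.2969 * np.sqrt(x) - 0.1260 * x - 0.3516 * x**2 + 0.2843 * x**3 + a4 * x**4
    )

    if camber > 0:
        m, p = camber, camber_pos
        yc = np.where(
            x < p,
            m / p**2 * (2 * p * x - x**2),
            m / (1 - p) ** 2 * ((1 - 2 * p) + 2 * p * x - x**2),
        )
        dyc = np.where(x < p, 2 * m / p**2 * (p - x), 2 * m / (1 - p) ** 2 * (p - x))
        theta = np.arctan(dyc)
        xu = x - yt * np.sin(theta)
        yu = yc + yt * np.cos(theta)
        xl = x + yt * np.sin(theta)
        yl = yc - yt * np.cos(theta)
    else:
        xu, yu, xl, yl = x, yt, x, -yt

    # Selig loop: TE -> upper -> LE -> lower -> TE (LE point shared once)
    coords = np.concatenate(
        [np.column_stack([xu, yu])[::-1], np.column_stack([xl, yl])[1:]]
    )
    if name is None:
        name = f"NACA {camber*100:.0f}{camber_pos*10:.0f}{thickness*100:02.0f}"
    return AirfoilShape(name=name, coords=coords, closed_te=closed_te)


def read_airfoil_dat(path: str | Path) -> AirfoilShape:
    """Read a Selig-style coordinate file (name line, then x y pairs TE->LE->TE)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise AirfoilFileError(f"{path}: empty file")
    name = lines[0].strip()
    pts: list[tuple[float, float]] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 2:
            raise AirfoilFileError(f"{path}:{lineno}: expected 'x y' pair, got {line!r}")
        try:
            pts.append((float(fields[0]), float(fields[1])))
        except ValueError as exc:
            raise AirfoilFileError(f"{path}:{lineno}: non-numeric coordinate {line!r}") from exc
    if len(pts) < 10:
        raise AirfoilFileError(f"{path}: too few coordinate pairs ({len(pts)})")
    coords = np.array(pts)
    x = coords[:, 0]
    i_le = int(np.argmin(x))
    # Selig order runs TE -> LE -> TE: x decreases to the LE then increases
    if not (np.all(np.diff(x[: i_le + 1]) <= 1e-9) and np.all(np.diff(x[i_le:]) >= -1e-9)):
        raise AirfoilFileError(f"{path}: coordinates are not in Selig TE->LE->TE order")
    # normalize chord to [0, 1]
    xmin, xmax = x.min(), x.max()
    coords = (coords - [xmin, 0.0]) / (xmax - xmin)
    closed = bool(np.allclose(coords[0], coords[-1], atol=1e-6))
    return AirfoilShape(name=name or path.stem, coords=coords, closed_te=closed)


def write_airfoil_dat(shape: AirfoilShape, path: str | Path) -> None:
    """Write a Selig-style coordinate file (full float precision, round-trip safe)."""
    lines = [shape.name]
    for x, y in shape.coords:
        lines.append(f"{x:.16g} {y:.16g}")
    Path(path).write_text("\n".join(lines) + "\n")
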