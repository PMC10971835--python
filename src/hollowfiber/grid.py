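"""Structured axisymmetric grid over the three-region representative unit.

The domain is the rectangle ``x in [0, L]``, ``r in [0, r3]`` revolved about
the axis.  Radial faces conform exactly to the two membrane interfaces, so
every cell carries exactly one region tag (tube / membrane / shell).  Radial
spacing inside the tube and shell bands is geometrically refined toward the
membrane, where fluxes and gradients concentrate; the membrane band itself is
uniform.  Axial spacing is uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridError

__all__ = ["Grid", "build_grid", "refine"]

TUBE, MEMBRANE, SHELL = "tube", "membrane", "shell"


@dataclass(frozen=True)
class Grid:
    """Cell-centred structured grid with axisymmetric metrics.

    ``x_faces`` has length nx+1 and spans [0, L]; ``r_faces`` spans [0, r3]
    and contains r1 and r2 exactly at the band boundaries.  Cells are indexed
    (i, j) with i axial and j radial; the rows ``j < nr_tube`` are tube,
    the next ``nr_mem`` rows are membrane, the rest shell.
    """

    x_faces: np.ndarray
    r_faces: np.ndarray
    nr_tube: int
    nr_mem: int
    nr_shell: int

    # derived metrics, filled in __post_init__
    xc: np.ndarray = field(init=False, repr=False)
    rc: np.ndarray = field(init=False, repr=False)
    dx: np.ndarray = field(init=False, repr=False)
    dr: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        xf, rf = np.asarray(self.x_faces, float), np.asarray(self.r_faces, float)
        if np.any(np.diff(xf) <= 0) or np.any(np.diff(rf) <= 0):
            raise GridError("face coordinates must be strictly increasing")
        object.__setattr__(self, "x_faces", xf)
        object.__setattr__(self, "r_faces", rf)
        object.__setattr__(self, "xc", 0.5 * (xf[:-1] + xf[1:]))
        object.__setattr__(self, "rc", 0.5 * (rf[:-1] + rf[1:]))
        object.__setattr__(self, "dx", np.diff(xf))
        object.__setattr__(self, "dr", np.diff(rf))
        if self.nr_tube + self.nr_mem + self.nr_shell != self.nr:
            raise GridError("band cell counts do not sum to the radial cell count")

    @property
    def nx(self) -> int:
        return len(self.x_faces) - 1

    @property
    def nr(self) -> int:
        return len(self.r_faces) - 1

    @property
    def n_cells(self) -> int:
        return self.nx * self.nr

    @property
    def j_mem_lo(self) -> int:
        """Radial face index of the inner membrane surface (r = r1)."""
        return self.nr_tube

    @property
    def j_mem_hi(self) -> int:
        """Radial face index of the outer membrane surface (r = r2)."""
        return self.nr_tube + self.nr_mem

    @property
    def r1(self) -> float:
        return float(self.r_faces[self.j_mem_lo])

    @property
    def r2(self) -> float:
        return float(self.r_faces[self.j_mem_hi])

    @property
    def region_rows(self) -> np.ndarray:
        """Region tag per radial row (length nr)."""
        return np.array(
            [TUBE] * self.nr_tube + [MEMBRANE] * self.nr_mem + [SHELL] * self.nr_shell
        )

    @property
    def region(self) -> np.ndarray:
        """Region tag per cell, shape (nx, nr)."""
        return np.broadcast_to(self.region_rows, (self.nx, self.nr)).copy()

    def row_is_membrane(self) -> np.ndarray:
        j = np.arange(self.nr)
        return (j >= self.j_mem_lo) & (j < self.j_mem_hi)

    def cell_volumes(self) -> np.ndarray:
        """Axisymmetric cell volumes pi (r_out^2 - r_in^2) dx, shape (nx, nr)."""
        ring = np.pi * (self.r_faces[1:] ** 2 - self.r_faces[:-1] ** 2)
        return np.outer(self.dx, ring)

    def face_area_x(self) -> np.ndarray:
        """Area of constant-x cell faces per radial row, pi (r_out^2 - r_in^2)."""
        return np.pi * (self.r_faces[1:] ** 2 - self.r_faces[:-1] ** 2)

    def face_area_r(self) -> np.ndarray:
        """Area of constant-r faces per (i, j_face): 2 pi r_face dx, shape (nx, nr+1)."""
        return 2.0 * np.pi * np.outer(self.dx, self.r_faces)


def _band_faces(a: float, b: float, n: int, stretch: float, fine_end: str) -> np.ndarray:
    """Faces of one radial band with geometric refinement toward fine_end ('lo'|'hi')."""
    if stretch == 1.0:
        f = np.linspace(a, b, n + 1)
    else:
        sizes = stretch ** np.arange(n)  # increasing
        if fine_end == "hi":
            sizes = sizes[::-1]  # smallest cells adjacent to b
        elif fine_end != "lo":
            raise GridError(f"fine_end must be 'lo' or 'hi', got {fine_end!r}")
        sizes = sizes * (b - a) / sizes.sum()
        f = a + np.concatenate([[0.0], np.cumsum(sizes)])
    f[0], f[-1] = a, b  # exact band endpoints
    return f


def build_grid(geometry, nx: int, nr_tube: int, nr_mem: int, nr_shell: int,
               stretch: float = 1.0) -> Grid:
    """Build the three-band grid for a representative-unit geometry.

    Tube-band cells shrink geometrically toward r1, shell-band cells toward
    r2 (ratio ``stretch`` between neighbours); the membrane band is uniform.
    """
    if min(nx, nr_tube, nr_mem, nr_shell) < 2:
        raise GridError("all cell counts must be >= 2")
    if stretch < 1.0:
        raise GridError(f"stretch ratio must be >= 1, got {stretch}")
    g = geometry
    x_faces = np.linspace(0.0, g.L, nx + 1)
    tube = _band_faces(0.0, g.r1, nr_tube, stretch, fine_end="hi")
    mem = _band_faces(g.r1, g.r2, nr_mem, 1.0, fine_end="lo")
    shell = _band_faces(g.r2, g.r3, nr_shell, stretch, fine_end="lo")
    r_faces = np.concatenate([tube, mem[1:], shell[1:]])
    return Grid(x_faces=x_faces, r_faces=r_faces,
                nr_tube=nr_tube, nr_mem=nr_mem, nr_shell=nr_shell)


def _split(faces: np.ndarray, factor: int) -> np.ndarray:
    """Insert factor-1 equally spaced faces inside every interval."""
    t = np.arange(factor) / factor
    pieces = faces[:-1, None] + np.diff(faces)[:, None] * t[None, :]
    return np.concatenate([pieces.ravel(), faces[-1:]])


def refine(grid: Grid, factor: int = 2) -> Grid:
    """Split every cell ``factor`` times in each direction; tags are inherited."""
    if factor < 2 or int(factor) != factor:
        raise GridError(f"refinement factor must be an integer >= 2, got {factor}")
    return Grid(
        x_faces=_split(grid.x_faces, factor),
        r_faces=_split(grid.r_faces, factor),
        nr_tube=grid.nr_tube * factor,
        nr_mem=grid.nr_mem * factor,
        nr_shell=grid.nr_shell * factor,
    )


def grid_for_case(case) -> Grid:
    """Grid at the case's solver settings."""
    s = case.solver
    return build_grid(case.geometry, s.nx, s.nr_tube, s.nr_mem, s.nr_shell,
                      stretch=s.stretch)
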