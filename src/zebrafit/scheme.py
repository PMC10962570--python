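"""Multi-echo diffusion acquisition schemes.

A scheme is the per-measurement sampling of the joint (b, TE) space: one
b-value (s/mm^2), one unit gradient direction and one echo time (ms) per
measurement.  Both signal models implemented here are isotropic, so the
directions never enter the forward signal; they are carried so schemes can
round-trip through the common bval/bvec-style text format and so direction
counts per shell are preserved.

The default scheme reproduces the integrated multi-TE diffusion ("ZEBRA")
placental protocol: 60 diffusion preparations, each read out at four echo
times (78, 114, 150, 186 ms), for 240 measurements.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field

import numpy as np

from .exceptions import SchemeParseError, SchemeValidationError

__all__ = [
    "AcquisitionScheme",
    "default_zebra_scheme",
    "load_scheme",
    "save_scheme",
    "ZEBRA_ECHO_TIMES_MS",
    "ZEBRA_SHELLS",
]

#: Echo times of the default placental protocol, ms.
ZEBRA_ECHO_TIMES_MS = (78.0, 114.0, 150.0, 186.0)

#: (b-value s/mm^2, number of gradient directions) per diffusion shell.
ZEBRA_SHELLS = (
    (5.0, 3), (10.0, 3), (18.0, 8), (25.0, 3), (36.0, 7), (50.0, 3),
    (100.0, 3), (200.0, 3), (400.0, 3), (600.0, 3), (800.0, 15),
    (1200.0, 3), (1600.0, 3),
)

_DIRECTION_NORM_TOL = 1e-6


@dataclass(frozen=True)
class AcquisitionScheme:
    """Per-measurement (b-value, direction, echo time) sampling table.

    Parameters
    ----------
    b_values : (n,) array
        Diffusion weightings, s/mm^2, all >= 0.
    directions : (n, 3) array
        Unit gradient directions (norm 1 within 1e-6).
    echo_times : (n,) array
        Echo times, ms, all > 0.

    Notes
    -----
    ``te_min`` is the shortest echo time in the scheme; the signal models
    decay with (TE - te_min), so the fitted s0 is the *observed* signal at
    ``te_min`` and b = 0, not an extrapolation to TE = 0.
    """

    b_values: np.ndarray
    directions: np.ndarray
    echo_times: np.ndarray
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float).ravel()
        d = np.asarray(self.directions, dtype=float)
        te = np.asarray(self.echo_times, dtype=float).ravel()
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", d.reshape(-1, 3))
        object.__setattr__(self, "echo_times", te)
        self.validate()

    def validate(self) -> None:
        b, d, te = self.b_values, self.directions, self.echo_times
        n = len(b)
        if not (len(te) == n and d.shape == (n, 3)):
            raise SchemeValidationError(
                f"column lengths differ: {n} b-values, {d.shape[0]} "
                f"directions, {len(te)} echo times"
            )
        if n < 2:
            raise SchemeValidationError(f"scheme needs >= 2 measurements, got {n}")
        if not np.all(np.isfinite(b)) or not np.all(np.isfinite(d)) or not np.all(np.isfinite(te)):
            raise SchemeValidationError("scheme contains non-finite entries")
        if np.any(b < 0):
            raise SchemeValidationError("negative b-value in scheme")
        if np.any(te <= 0):
            raise SchemeValidationError("non-positive echo time in scheme")
        norms = np.linalg.norm(d, axis=1)
        if np.any(np.abs(norms - 1.0) > _DIRECTION_NORM_TOL):
            worst = int(np.argmax(np.abs(norms - 1.0)))
            raise SchemeValidationError(
                f"direction {worst} has norm {norms[worst]:.8f}, expected 1"
            )
        if np.unique(te).size < 2:
            raise SchemeValidationError(
                "joint T2*-diffusion fitting needs >= 2 distinct echo times"
            )
        if np.unique(b).size < 2:
            raise SchemeValidationError(
                "joint T2*-diffusion fitting needs >= 2 distinct b-values"
            )

    def __len__(self) -> int:
        return len(self.b_values)

    @property
    def te_min(self) -> float:
        """Shortest echo time in the scheme, ms."""
        return float(np.min(self.echo_times))

    @property
    def n_measurements(self) -> int:
        return len(self.b_values)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AcquisitionScheme):
            return NotImplemented
        return (
            self.b_values.shape == other.b_values.shape
            and np.array_equal(self.b_values, other.b_values)
            and np.array_equal(self.directions, other.directions)
            and np.array_equal(self.echo_times, other.echo_times)
        )

    def approx_equal(self, other: "AcquisitionScheme", rtol: float = 1e-5,
                     atol: float = 1e-8) -> bool:
        """Numeric-column equality at file round-trip precision."""
        return (
            len(self) == len(other)
            and np.allclose(self.b_values, other.b_values, rtol=rtol, atol=atol)
            and np.allclose(self.directions, other.directions, rtol=rtol, atol=atol)
            and np.allclose(self.echo_times, other.echo_times, rtol=rtol, atol=atol)
        )

    def as_array(self) -> np.ndarray:
        """(n, 5) float array with columns (gx, gy, gz, b, TE_ms)."""
        return np.column_stack([self.directions, self.b_values, self.echo_times])


def _spherical_spiral_directions(n: int) -> np.ndarray:
    """``n`` deterministic, roughly uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    d = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def default_zebra_scheme() -> AcquisitionScheme:
    """The default combined T2*-diffusion placental protocol.

    Sixty diffusion preparations — 3 directions at each of b = 5, 10, 25,
    50, 100, 200, 400, 600, 1200, 1600 s/mm^2, plus 8 at b = 18, 7 at
    b = 36 and 15 at b = 800 — each acquired at TE = 78, 114, 150 and
    186 ms, giving 240 measurements with te_min = 78 ms.

    Directions are generated per shell by a deterministic golden-angle
    spherical spiral; the isotropic models are insensitive to them.
    """
    bs, dirs, tes = [], [], []
    for b, n_dir in ZEBRA_SHELLS:
        shell_dirs = _spherical_spiral_directions(n_dir)
        for k in range(n_dir):
            for te in ZEBRA_ECHO_TIMES_MS:
                bs.append(b)
                dirs.append(shell_dirs[k])
                tes.append(te)
    return AcquisitionScheme(
        b_values=np.array(bs),
        directions=np.array(dirs),
        echo_times=np.array(tes),
        metadata={"protocol": "zebra-placenta-default"},
    )


def load_scheme(path: str | os.PathLike) -> AcquisitionScheme:
    """Read a scheme from a 5-column text file (gx gy gz b TE_ms).

    Blank lines and ``#`` comments are ignored.  Raises
    :class:`SchemeParseError` naming the offending line on malformed input
    and :class:`SchemeValidationError` if the parsed table violates a
    scheme invariant.
    """
    rows = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise SchemeParseError(
                    f"{path}: line {lineno}: expected 5 columns "
                    f"(gx gy gz b TE_ms), got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise SchemeParseError(
                    f"{path}: line {lineno}: non-numeric entry ({exc})"
                ) from None
    if not rows:
        raise SchemeParseError(f"{path}: no data rows")
    arr = np.array(rows, dtype=float)
    return AcquisitionScheme(
        b_values=arr[:, 3], directions=arr[:, :3], echo_times=arr[:, 4],
        metadata={"source": str(path)},
    )


def save_scheme(scheme: AcquisitionScheme, path: str | os.PathLike) -> None:
    """Write a scheme as 5-column text; round-trips through ``load_scheme``."""
    scheme.validate()
    buf = io.StringIO()
    buf.write("# gx gy gz b[s/mm^2] TE[ms]\n")
    for (gx, gy, gz), b, te in zip(scheme.directions, scheme.b_values,
                                   scheme.echo_times):
        buf.write(f"{gx:.8g} {gy:.8g} {gz:.8g} {b:.8g} {te:.8g}\n")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
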