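"""Coordinate-ensemble analysis: selections, superposition, RMSD and RMSF.

Conventions (the package's own, stated once here and in output headers):
RMSD is computed after unweighted least-squares (Kabsch) superposition of the
fit selection; RMSF within a time window superposes every frame onto the
window-mean structure (iterated to self-consistency) and reports, per site,
sqrt(<|r_i - <r_i>|^2>) of the 3D displacement — for iid per-axis Gaussian
jitter of s.d. sigma this is sigma*sqrt(3).  Windowed analyses drop a final
partial window rather than padding.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .fixtures import CoordinateEnsemble

__all__ = [
    "ResidueSelection",
    "parse_residue_selection",
    "kabsch_rmsd",
    "superpose",
    "rmsd_series",
    "rmsf_windows",
    "RMSFTable",
]

_DASHES = "–—−‐"  # en/em dash, minus, hyphen variants
_TOKEN = re.compile(r"^(\d+)(?:-(\d+))?$")


@dataclass(frozen=True)
class ResidueSelection:
    """Sorted, unique residue indices plus the text they came from."""

    indices: np.ndarray
    source: str

    def __len__(self) -> int:
        return int(self.indices.size)

    def to_string(self) -> str:
        """Canonical comma-separated range string (e.g. ``"1-3,7"``)."""
        parts = []
        idx = self.indices
        start = prev = int(idx[0])
        for v in idx[1:]:
            v = int(v)
            if v == prev + 1:
                prev = v
                continue
            parts.append(f"{start}-{prev}" if prev > start else f"{start}")
            start = prev = v
        parts.append(f"{start}-{prev}" if prev > start else f"{start}")
        return ",".join(parts)

    def zero_based(self) -> np.ndarray:
        return self.indices - 1


def parse_residue_selection(text: str) -> ResidueSelection:
    """Parse a comma-separated list of residue indices and inclusive ranges.

    Accepts hyphens or en-dashes as the range separator (printed tables often
    use the latter).  Duplicate indices are collapsed; a descending range or
    malformed token raises ``ValueError``.
    """
    cleaned = str(text)
    for ch in _DASHES:
        cleaned = cleaned.replace(ch, "-")
    indices: set[int] = set()
    for raw in cleaned.split(","):
        token = raw.strip().replace(" ", "")
        if not token:
            continue
        m = _TOKEN.match(token)
        if m is None:
            raise ValueError(f"malformed residue token {raw.strip()!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        if hi < lo:
            raise ValueError(f"descending range {raw.strip()!r}")
        indices.update(range(lo, hi + 1))
    if not indices:
        raise ValueError("empty residue selection")
    return ResidueSelection(np.array(sorted(indices), dtype=int), source=str(text))


def _kabsch_rotation(ref: np.ndarray, mov: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation + translation mapping mov onto ref.

    Returns (rotation, ref_centroid, mov_centroid) with
    aligned = (mov - mov_centroid) @ rotation.T + ref_centroid.
    """
    if ref.shape != mov.shape or ref.shape[0] < 3:
        raise ValueError("need two equal coordinate sets with >= 3 sites")
    c_ref = ref.mean(axis=0)
    c_mov = mov.mean(axis=0)
    a = ref - c_ref
    b = mov - c_mov
    h = b.T @ a
    u, s, vt = np.linalg.svd(h)
    # collinear / degenerate sets leave the rotation underdetermined
    if s[1] <= 1e-10 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) coordinate set; rotation undefined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return rot, c_ref, c_mov


def kabsch_rmsd(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Least-squares superposition of ``frame_b`` onto ``frame_a``.

    Returns ``((rotation, translation), rmsd)`` where the aligned copy of b
    is ``frame_b @ rotation.T + translation`` and the RMSD is unweighted over
    the selection (all sites if ``selection`` is None; zero-based indices).
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        a_fit, b_fit = a[sel], b[sel]
    else:
        a_fit, b_fit = a, b
    rot, c_ref, c_mov = _kabsch_rotation(a_fit, b_fit)
    translation = c_ref - c_mov @ rot.T
    aligned = b_fit @ rot.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - a_fit) ** 2, axis=-1))))
    return (rot, translation), rmsd


def superpose(
    reference: np.ndarray,
    frame: np.ndarray,
    fit_selection: np.ndarray | None = None,
) -> np.ndarray:
    """Return ``frame`` rigidly superposed onto ``reference``.

    The transform is fitted on ``fit_selection`` (zero-based indices, all
    sites if None) and applied to every site.
    """
    ref = np.asarray(reference, dtype=float)
    mov = np.asarray(frame, dtype=float)
    sel = np.arange(ref.shape[0]) if fit_selection is None else np.asarray(fit_selection, int)
    rot, c_ref, c_mov = _kabsch_rotation(ref[sel], mov[sel])
    return (mov - c_mov) @ rot.T + c_ref


def rmsd_series(
    ensemble: "CoordinateEnsemble",
    reference_frame: int | np.ndarray = 0,
    fit_selection: np.ndarray | None = None,
    report_selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame RMSD from a reference after superposition.

    Each frame is superposed onto the reference using ``fit_selection`` and
    the RMSD is reported over ``report_selection`` (both zero-based; None
    means all sites).  This supports the fit-on-whole / report-on-gate
    pattern used for gate-opening analysis.  Returns (times, rmsd).
    """
    coords = ensemble.coords
    ref = (
        coords[reference_frame]
        if isinstance(reference_frame, (int, np.integer))
        else np.asarray(reference_frame, dtype=float)
    )
    rep = (
        np.arange(coords.shape[1])
        if report_selection is None
        else np.asarray(report_selection, dtype=int)
    )
    if rep.size == 0:
        raise ValueError("empty report selection")
    out = np.empty(coords.shape[0])
    for t in range(coords.shape[0]):
        aligned = superpose(ref, coords[t], fit_selection)
        out[t] = np.sqrt(np.mean(np.sum((aligned[rep] - ref[rep]) ** 2, axis=-1)))
    return ensemble.times(), out


@dataclass
class RMSFTable:
    """Per-site RMSF per time window per run, with the run average.

    ``per_run`` has shape (n_runs, n_windows, n_sites); ``run_average`` is
    the arithmetic mean over runs.
    """

    per_run: np.ndarray
    site_labels: np.ndarray
    window_frames: int
    dropped_frames_per_run: list[int] = field(default_factory=list)

    @property
    def run_average(self) -> np.ndarray:
        return self.per_run.mean(axis=0)

    @property
    def n_windows(self) -> int:
        return self.per_run.shape[1]


def _window_rmsf(frames: np.ndarray, n_iter: int = 3) -> np.ndarray:
    """RMSF per site within one window, superposing onto the window mean."""
    aligned = frames.copy()
    for _ in range(n_iter):
        mean = aligned.mean(axis=0)
        aligned = np.stack([superpose(mean, f) for f in aligned])
    mean = aligned.mean(axis=0)
    return np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=-1), axis=0))


def rmsf_windows(
    ensembles: Sequence["CoordinateEnsemble"],
    window_frames: int,
) -> RMSFTable:
    """Windowed per-site RMSF averaged over independent runs.

    Every run is cut into consecutive full windows of ``window_frames``
    frames (a trailing partial window is dropped); within each window the
    frames are superposed onto the window-mean structure and the per-site
    RMSF is computed; the table's run average is the arithmetic mean over
    runs, window by window.
    """
    if not ensembles:
        raise ValueError("need at least one run")
    n_windows = min(e.n_frames // window_frames for e in ensembles)
    if n_windows < 1:
        raise ValueError(
            f"window of {window_frames} frames is longer than the shortest run"
        )
    n_sites = ensembles[0].n_sites
    per_run = np.empty((len(ensembles), n_windows, n_sites))
    dropped = []
    for r, ens in enumerate(ensembles):
        if ens.n_sites != n_sites:
            raise ValueError("all runs must share the same site count")
        for w in range(n_windows):
            chunk = ens.coords[w * window_frames : (w + 1) * window_frames]
            per_run[r, w] = _window_rmsf(chunk)
        dropped.append(ens.n_frames - n_windows * window_frames)
    return RMSFTable(
        per_run=per_run,
        site_labels=ensembles[0].site_labels.copy(),
        window_frames=window_frames,
        dropped_frames_per_run=dropped,
    )
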