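"""Blind source separation and anatomically guided signal selection.

The array records every forearm muscle on many electrodes at once, so each
channel is a linear mixture of muscle sources plus interference.  A single
model super-Gaussian ICA (FastICA with a logcosh contrast, after a
rank-truncating PCA whitening) recovers the sources; the mixing-matrix
column of each component, placed on the electrode grid, gives a topology
map used to flag implausible components (motion noise spreads over a large
area; a detached sensor shows one dominant electrode with an opposite-sign
neighbour).  Candidate components and channels are ranked by the Pearson
correlation between their rectified low-pass envelopes and the
direction-specific ground-truth angle (flexion target max(theta, 0),
extension target max(−theta, 0)); channel candidates are restricted to the
anatomical mask of the finger.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import kurtosis
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .evaluate import correlation_coefficient
from .kinematics import FingerTrajectory
from .layout import ArrayLayout, ChannelMask
from .preprocess import EmgRecording, EnvelopeSet, envelope

RANK_EV_THRESHOLD = 1.0 - 1e-6  # explained-variance fraction kept by whitening
TOP_CANDIDATES = 16


@dataclass
class ICDecomposition:
    """Linear decomposition X ≈ mean + mixing @ sources."""

    unmixing: np.ndarray  # components × channels
    mixing: np.ndarray  # channels × components
    sources: np.ndarray  # components × samples
    mean: np.ndarray  # per-channel mean removed before unmixing
    fs: float
    retained_rank: int
    seed: int
    converged: bool = True
    notes: tuple[str, ...] = ()

    def transform(self, data: np.ndarray) -> np.ndarray:
        """Apply the unmixing to new channels × samples data."""
        return self.unmixing @ (data - self.mean[:, None])

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]


@dataclass
class Candidate:
    ident: object  # component index or channel label
    cc: float
    flags: tuple[str, ...] = ()


@dataclass
class SelectionResult:
    finger: str
    direction: str
    chosen: object
    cc: float
    candidates: list[Candidate] = field(default_factory=list)


def fit_ica(
    processed: EmgRecording | np.ndarray,
    n_components: int | str = "auto",
    seed: int = 0,
    fs: float | None = None,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> ICDecomposition:
    """Whiten to the retained rank, then run a super-Gaussian single-model ICA.

    ``n_components='auto'`` keeps the PCA rank explaining 1 − 1e−6 of the
    variance (rank-deficient inputs, e.g. after average re-referencing or
    with duplicated channels, are handled by the truncation).  The mixing
    matrix is the pseudo-inverse of the composed unmixing.  Deterministic
    given ``seed``.  Non-convergence and near-Gaussian sources (for which
    ICA is not identifiable) are reported through ``converged`` / ``notes``
    rather than raising.
    """
    if isinstance(processed, EmgRecording):
        X = processed.data
        fs = processed.fs
    else:
        X = np.asarray(processed, dtype=float)
        if fs is None:
            raise ValueError("fs is required when passing a bare matrix")
    n_ch, n_samp = X.shape
    if n_samp < 4 * n_ch:
        raise ValueError("need samples >> channels for a stable decomposition")
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]

    cov = (Xc @ Xc.T) / n_samp
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    if total <= 0:
        raise ValueError("input has zero variance (rank 0)")
    cum = np.cumsum(evals) / total
    rank = int(np.searchsorted(cum, RANK_EV_THRESHOLD) + 1)
    rank = min(rank, int(np.sum(evals > 1e-12 * evals[0])))
    if n_components != "auto":
        rank = min(rank, int(n_components))
    if rank < 1:
        raise ValueError("retained rank is zero")

    whiten = evecs[:, :rank].T / np.sqrt(evals[:rank])[:, None]  # rank × channels
    Z = whiten @ Xc

    ica = FastICA(
        n_components=rank,
        whiten=False,
        fun="logcosh",
        random_state=seed,
        max_iter=max_iter,
        tol=tol,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ica.fit(Z.T)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    unmixing = ica.components_ @ whiten  # rank × channels
    mixing = np.linalg.pinv(unmixing)
    sources = unmixing @ Xc

    notes = []
    kurt = kurtosis(sources, axis=1, fisher=True)
    if np.median(np.abs(kurt)) < 0.2:
        notes.append("near-gaussian sources: separation not identifiable")
        converged = False
    return ICDecomposition(
        unmixing=unmixing,
        mixing=mixing,
        sources=sources,
        mean=mean,
        fs=float(fs),
        retained_rank=rank,
        seed=seed,
        converged=converged,
        notes=tuple(notes),
    )


def amari_index(estimated_unmixing: np.ndarray, true_mixing: np.ndarray) -> float:
    """Permutation/scale-invariant separation error; 0 iff W·A is a scaled permutation."""
    P = np.abs(np.asarray(estimated_unmixing) @ np.asarray(true_mixing))
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"W·A must be square, got {P.shape}")
    N = P.shape[0]
    if N < 2:
        return 0.0
    row = (P.sum(axis=1) / P.max(axis=1) - 1).sum()
    col = (P.sum(axis=0) / P.max(axis=0) - 1).sum()
    return float((row + col) / (2 * N * (N - 1)))


@dataclass
class TopologyMap:
    component: int
    weights: np.ndarray  # per-channel mixing weights
    grids: dict  # side → (4, 12) weight grid
    spread: float
    bipolarity: int
    flags: tuple[str, ...]


def ic_topology(decomp: ICDecomposition, layout: ArrayLayout, component: int) -> TopologyMap:
    """Mixing weights on the electrode grid plus artifact heuristics.

    ``spread`` is the fraction of channels whose |weight| reaches half the
    maximum — a large value means the component paints most of the array
    (motion noise).  ``bipolarity`` is 1 when the single dominant channel
    has an opposite-sign grid neighbour at ≥ half the maximum (detached
    sensor signature).
    """
    if component >= decomp.retained_rank:
        raise IndexError("component index beyond retained rank")
    w = decomp.mixing[:, component]
    if w.shape[0] != len(layout):
        raise ValueError("decomposition channel count does not match layout")
    wmax = np.abs(w).max()
    if wmax == 0:
        spread = 0.0
        bipolar = 0
    else:
        spread = float(np.mean(np.abs(w) >= 0.5 * wmax))
        dom = int(np.argmax(np.abs(w)))
        dom_label = layout.labels[dom]
        bipolar = 0
        for nb in layout.neighbors(dom_label):
            wn = w[layout.index_of(nb)]
            if np.sign(wn) == -np.sign(w[dom]) and np.abs(wn) >= 0.5 * wmax:
                bipolar = 1
                break
    flags = []
    if spread > 0.5:
        flags.append("motion-noise")
    if bipolar:
        flags.append("detach")
    grids = {side: layout.grid_map(w, side) for side in ("flexor", "extensor")}
    return TopologyMap(
        component=component,
        weights=w,
        grids=grids,
        spread=spread,
        bipolarity=bipolar,
        flags=tuple(flags),
    )


def plot_topology(topo: TopologyMap, path=None):
    """Render a component's weight map on the two electrode panels.

    Returns the matplotlib figure; saves it to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(6, 4), constrained_layout=True)
    vmax = max(np.nanmax(np.abs(g)) for g in topo.grids.values()) or 1.0
    for ax, (side, grid) in zip(axes, topo.grids.items()):
        im = ax.imshow(grid, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="equal")
        ax.set_title(f"{side} panel")
        ax.set_xlabel("column (proximal → distal)")
        ax.set_ylabel("row")
    fig.colorbar(im, ax=axes, shrink=0.8, label="mixing weight")
    flags = ", ".join(topo.flags) if topo.flags else "no flags"
    fig.suptitle(f"IC {topo.component} — spread {topo.spread:.2f}, {flags}")
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def direction_target(traj: FingerTrajectory, finger: str, direction: str) -> np.ndarray:
    """Half-wave-rectified angle: flexion keeps θ>0 lobes, extension −θ>0."""
    theta = traj.finger(finger)
    if direction == "flexion":
        return np.maximum(theta, 0.0)
    if direction == "extension":
        return np.maximum(-theta, 0.0)
    raise KeyError(f"unknown direction {direction!r}")


def _cc_against_target(env_rows: np.ndarray, target: np.ndarray) -> np.ndarray:
    n = min(env_rows.shape[1], target.size)
    out = np.empty(env_rows.shape[0])
    for i, row in enumerate(env_rows):
        out[i] = correlation_coefficient(row[:n], target[:n])
    return out


def rank_components_by_cc(
    decomp: ICDecomposition,
    traj: FingerTrajectory,
    finger: str,
    direction: str,
    layout: ArrayLayout | None = None,
    component_envelopes: EnvelopeSet | None = None,
    top: int = TOP_CANDIDATES,
) -> SelectionResult:
    """Rank components by |CC| of their envelope against the motion target.

    Envelopes are computed with the standard settings at the decomposition
    rate unless precomputed ones are supplied (they must then be aligned
    with the trajectory).  The top candidates carry topology artifact flags
    when a layout is given; the chosen component is the highest-|CC|
    unflagged candidate (falling back to the overall best if all are
    flagged), ties broken toward the lower component index.
    """
    if decomp.n_components == 0:
        raise ValueError("empty decomposition")
    if component_envelopes is None:
        component_envelopes = envelope(
            decomp.sources, decomp.fs, source_kind="independent_component"
        )
    target = direction_target(traj, finger, direction)
    cc = _cc_against_target(component_envelopes.envelopes, target)
    cc = np.nan_to_num(cc, nan=0.0)
    order = np.lexsort((np.arange(cc.size), -np.abs(cc)))[:top]
    candidates = []
    for idx in order:
        flags = ic_topology(decomp, layout, int(idx)).flags if layout is not None else ()
        candidates.append(Candidate(ident=int(idx), cc=float(cc[idx]), flags=flags))
    chosen = next((c for c in candidates if not c.flags), candidates[0])
    return SelectionResult(
        finger=finger,
        direction=direction,
        chosen=chosen.ident,
        cc=chosen.cc,
        candidates=candidates,
    )


def select_channels(
    envelopes: EnvelopeSet,
    traj: FingerTrajectory,
    mask: ChannelMask,
    finger: str,
    direction: str,
    layout: ArrayLayout | None = None,
) -> SelectionResult:
    """Pick the mask channel whose envelope best tracks the motion target.

    Ties in |CC| are broken toward the lower grid row, then column (needs a
    layout; otherwise mask order decides).
    """
    labels = mask.labels(finger, direction)
    target = direction_target(traj, finger, direction)
    rows = np.stack([envelopes.get(lab) for lab in labels])
    cc = np.nan_to_num(_cc_against_target(rows, target), nan=0.0)
    if layout is not None:
        tie = [(layout.electrode(lab).row, layout.electrode(lab).col) for lab in labels]
    else:
        tie = list(range(len(labels)))
    order = sorted(range(len(labels)), key=lambda i: (-np.abs(cc[i]), tie[i]))
    candidates = [Candidate(ident=labels[i], cc=float(cc[i])) for i in order]
    best = candidates[0]
    return SelectionResult(
        finger=finger,
        direction=direction,
        chosen=best.ident,
        cc=best.cc,
        candidates=candidates,
    )
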