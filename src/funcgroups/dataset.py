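"""Population fluorescence dataset container and on-disk format.

A recording is a neurons x frames matrix of per-neuron normalized traces plus
per-frame annotations: the stimulus label (grey or one of 12 drifting-grating
directions), the running speed, and the trial (block) index.  Stimulus blocks
are identical repeats of one pseudo-random direction sequence, which is what
lets trial-wise quantities (leave-one-out trial means, block-mean traces) be
aligned framewise.

On disk a dataset is a directory with::

    traces.h5   HDF5 file with dataset "traces", neurons x frames
    frames.csv  columns frame_index, block_index, stimulus_label, running_speed
    meta.json   frame_rate_hz, n_neurons, seed, tuned flags, ground truth

All indices are 0-based; frame intervals are half-open.
"""
from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Stimulus label alphabet: grey plus the 12 drifting-grating directions.
GREY = 0
DIRECTIONS_DEG = tuple(range(30, 361, 30))
N_CONDITIONS = 13
LABEL_NAMES = ("grey",) + tuple(str(d) for d in DIRECTIONS_DEG)


def label_code(name: str | int) -> int:
    """Map a label name ('grey', '30', ..., '360' or degrees int) to its code."""
    if isinstance(name, (int, np.integer)) and name != 0:
        name = str(int(name))
    if name in (0, "grey"):
        return GREY
    return LABEL_NAMES.index(str(name))


@dataclass
class Presentation:
    """One contiguous run of grating frames (half-open [start, stop))."""

    start: int
    stop: int
    label: int
    block: int


@dataclass
class FluorescenceDataset:
    """Per-neuron normalized population fluorescence with trial structure.

    Parameters
    ----------
    traces : ndarray, shape (n_neurons, n_frames)
        Per-neuron normalized (z-scored) fluorescence.
    frame_rate_hz : float
        Imaging rate in frames/second.
    labels : ndarray of int, shape (n_frames,)
        Stimulus condition code per frame (0 = grey, k = direction 30*k deg).
    running_speed : ndarray, shape (n_frames,)
        Rotary-encoder running speed per frame (arbitrary units, >= 0).
    block_index : ndarray of int, shape (n_frames,)
        Trial (block) index per frame; contiguous, starting at 0.
    tuned : ndarray of bool, shape (n_neurons,), optional
        Per-neuron direction/orientation tuning flag; may be None for real
        data, in which case a surrogate tuning test is applied downstream.
    flat_neurons : ndarray of bool, optional
        Neurons whose raw trace had zero variance (left at 0, not z-scored).
    """

    traces: np.ndarray
    frame_rate_hz: float
    labels: np.ndarray
    running_speed: np.ndarray
    block_index: np.ndarray
    tuned: np.ndarray | None = None
    flat_neurons: np.ndarray | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.traces = np.asarray(self.traces, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.running_speed = np.asarray(self.running_speed, dtype=float)
        self.block_index = np.asarray(self.block_index, dtype=int)
        n, t = self.traces.shape
        for name in ("labels", "running_speed", "block_index"):
            if len(getattr(self, name)) != t:
                raise ValueError(f"{name} length != n_frames ({t})")
        if not np.isfinite(self.traces).all():
            raise ValueError("traces contain non-finite values")
        if (np.diff(self.block_index) < 0).any():
            raise ValueError("block_index must be non-decreasing (contiguous blocks)")
        if self.tuned is not None:
            self.tuned = np.asarray(self.tuned, dtype=bool)
            if len(self.tuned) != n:
                raise ValueError("tuned length != n_neurons")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def n_blocks(self) -> int:
        return int(self.block_index.max()) + 1

    def block_slices(self) -> list[slice]:
        """Half-open frame slice of each block, in block order."""
        edges = np.flatnonzero(np.diff(self.block_index)) + 1
        starts = np.concatenate([[0], edges])
        stops = np.concatenate([edges, [self.n_frames]])
        return [slice(int(a), int(b)) for a, b in zip(starts, stops)]

    def aligned_blocks(self) -> np.ndarray:
        """Traces reshaped to (n_blocks, n_neurons, frames_per_block).

        Blocks are aligned by within-block frame position.  Unequal block
        lengths are truncated to the shortest block (logged); identical-repeat
        protocols produce equal blocks so this is a no-op for synthetic data.
        """
        sls = self.block_slices()
        lengths = [s.stop - s.start for s in sls]
        tb = min(lengths)
        if len(set(lengths)) > 1:
            logger.warning("unequal block lengths %s; truncating to %d", lengths, tb)
        return np.stack([self.traces[:, s.start : s.start + tb] for s in sls])

    def block_labels(self) -> np.ndarray:
        """Per-frame labels of one (truncated) block; identical across blocks."""
        sls = self.block_slices()
        tb = min(s.stop - s.start for s in sls)
        first = self.labels[sls[0].start : sls[0].start + tb]
        for s in sls[1:]:
            if not np.array_equal(self.labels[s.start : s.start + tb], first):
                raise ValueError("block label sequences differ; blocks are not repeats")
        return first

    # -- stimulus structure ------------------------------------------------
    def grating_mask(self) -> np.ndarray:
        return self.labels != GREY

    def presentations(self) -> list[Presentation]:
        """Contiguous grating presentations (label constant, grey excluded)."""
        out: list[Presentation] = []
        lab, blk = self.labels, self.block_index
        t = 0
        while t < self.n_frames:
            if lab[t] == GREY:
                t += 1
                continue
            start = t
            while t < self.n_frames and lab[t] == lab[start] and blk[t] == blk[start]:
                t += 1
            out.append(Presentation(start, t, int(lab[start]), int(blk[start])))
        return out

    def first_frames_of_blocks(self) -> np.ndarray:
        """Mask of the first frame of every block (lag-1 feature undefined)."""
        mask = np.zeros(self.n_frames, dtype=bool)
        for s in self.block_slices():
            mask[s.start] = True
        return mask

    # -- IO ------------------------------------------------------------------
    def save(self, outdir: str | pathlib.Path) -> pathlib.Path:
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with h5py.File(outdir / "traces.h5", "w") as f:
            f.create_dataset("traces", data=self.traces)
        pd.DataFrame(
            {
                "frame_index": np.arange(self.n_frames),
                "block_index": self.block_index,
                "stimulus_label": [LABEL_NAMES[c] for c in self.labels],
                "running_speed": self.running_speed,
            }
        ).to_csv(outdir / "frames.csv", index=False)
        meta = dict(self.meta)
        meta.update(
            frame_rate_hz=self.frame_rate_hz,
            n_neurons=self.n_neurons,
            seed=self.seed,
        )
        if self.tuned is not None:
            meta["tuned"] = self.tuned.astype(int).tolist()
        if self.flat_neurons is not None:
            meta["flat_neurons"] = self.flat_neurons.astype(int).tolist()
        (outdir / "meta.json").write_text(json.dumps(meta, indent=1))
        return outdir

    @classmethod
    def load(cls, indir: str | pathlib.Path) -> "FluorescenceDataset":
        indir = pathlib.Path(indir)
        with h5py.File(indir / "traces.h5", "r") as f:
            traces = f["traces"][...]
        frames = pd.read_csv(indir / "frames.csv")
        meta = json.loads((indir / "meta.json").read_text())
        tuned = meta.pop("tuned", None)
        flat = meta.pop("flat_neurons", None)
        return cls(
            traces=traces,
            frame_rate_hz=float(meta.pop("frame_rate_hz")),
            labels=np.array([label_code(s) for s in frames["stimulus_label"]]),
            running_speed=frames["running_speed"].to_numpy(),
            block_index=frames["block_index"].to_numpy(),
            tuned=None if tuned is None else np.asarray(tuned, bool),
            flat_neurons=None if flat is None else np.asarray(flat, bool),
            seed=meta.pop("seed", None),
            meta=meta,
        )
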