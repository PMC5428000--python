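"""Time-ordered feature trajectories.

The whole pipeline operates on :class:`FeatureTrajectory` objects: a frames x
features real matrix sampled at a fixed frame spacing, with one label per
feature column. Featurizers produce them, tICA consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTrajectory"]


@dataclass
class FeatureTrajectory:
    """Real-valued feature time series at fixed frame spacing.

    Parameters
    ----------
    data : ndarray, shape (n_frames, n_features)
        Feature values. Must be finite.
    dt : float
        Frame spacing in the pipeline's time unit (conventionally ns).
    labels : list of str
        One label per feature column (e.g. ``"CA:145"`` for a residue-pair
        distance).
    metadata : dict
        Free-form provenance (generator spec, seed, source files).
    """

    data: np.ndarray
    dt: float = 1.0
    labels: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (frames x features) array")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(
                f"non-finite feature value at frame {bad[0]}, column {bad[1]}"
            )
        if self.dt <= 0:
            raise ValueError("frame spacing dt must be positive")
        if self.labels is None:
            self.labels = [f"f{i}" for i in range(self.data.shape[1])]
        if len(self.labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[1]} columns"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Return the trajectory as a DataFrame indexed by time."""
        index = pd.Index(np.arange(self.n_frames) * self.dt, name="time")
        return pd.DataFrame(self.data, index=index, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, dt: float | None = None) -> "FeatureTrajectory":
        df = pd.read_csv(path, index_col=0)
        if dt is None:
            t = df.index.to_numpy(dtype=float)
            dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
        return cls(df.to_numpy(dtype=float), dt=dt, labels=list(df.columns))

    def to_npz(self, path) -> None:
        np.savez(path, data=self.data, dt=self.dt,
                 labels=np.asarray(self.labels, dtype=object))

    @classmethod
    def from_npz(cls, path) -> "FeatureTrajectory":
        with np.load(path, allow_pickle=True) as f:
            return cls(f["data"], dt=float(f["dt"]), labels=list(f["labels"]))
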