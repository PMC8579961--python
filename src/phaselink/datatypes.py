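"""Core containers for epoched EEG, frequency bands, ROI schemes and cohorts.

All pipeline stages consume the canonical ``(channel, epoch, sample)`` array
layout held by :class:`EpochedRecording`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "EpochedRecording",
    "BandSpec",
    "DEFAULT_BANDS",
    "ROIScheme",
    "DEFAULT_ROI",
    "SCALP_60",
    "NEUROSCAN_64",
    "Subject",
    "CohortDataset",
    "PipelineConfig",
]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with edges in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got "
                f"({self.f_lo}, {self.f_hi})"
            )

    def validate_for(self, fs: float) -> None:
        """Raise if the band is not strictly below the Nyquist frequency."""
        if self.f_hi >= fs / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.f_hi} Hz >= Nyquist "
                f"({fs / 2} Hz)"
            )


#: The six canonical resting-EEG analysis bands.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 4.0),
    BandSpec("theta", 4.0, 7.0),
    BandSpec("low_alpha", 8.0, 10.0),
    BandSpec("upper_alpha", 10.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
    BandSpec("gamma", 30.0, 45.0),
)


# NeuroScan 64-channel Quik-Cap labels (extended 10-10). The last four are
# non-scalp (mastoids and cerebellar leads) and are dropped by default before
# connectivity analysis.
NEUROSCAN_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AF3", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
    "M1", "M2", "CB1", "CB2",
)

#: The 60 scalp channels analysed by default.
SCALP_60: tuple[str, ...] = NEUROSCAN_64[:60]


@dataclass
class EpochedRecording:
    """Multichannel epoched EEG: ``data[channel, epoch, sample]`` in microvolts."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    epoch_length_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (channel, epoch, sample), got shape {self.data.shape}"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels but "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN samples")
        expected = int(round(self.epoch_length_s * self.fs))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.epoch_length_s}s at fs={self.fs} implies "
                f"{expected} samples/epoch, data has {self.data.shape[2]}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select_channels(self, keep: Sequence[str]) -> "EpochedRecording":
        """Restrict (and reorder) channels to ``keep``.

        Raises ``KeyError`` naming any label absent from the recording.
        """
        index = {label: i for i, label in enumerate(self.channel_labels)}
        unknown = [lab for lab in keep if lab not in index]
        if unknown:
            raise KeyError(f"channel labels not in recording: {unknown}")
        rows = [index[lab] for lab in keep]
        return EpochedRecording(
            data=self.data[rows],
            fs=self.fs,
            channel_labels=tuple(keep),
            epoch_length_s=self.epoch_length_s,
        )


@dataclass(frozen=True)
class ROIScheme:
    """Mapping of region names to disjoint electrode-label groups."""

    regions: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "regions",
            {name: tuple(labels) for name, labels in self.regions.items()},
        )
        seen: set[str] = set()
        for name, labels in self.regions.items():
            overlap = seen.intersection(labels)
            if overlap:
                raise ValueError(f"region {name!r} re-uses electrodes {sorted(overlap)}")
            seen.update(labels)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.regions)

    def electrodes(self) -> tuple[str, ...]:
        return tuple(lab for labels in self.regions.values() for lab in labels)

    def validate_against(self, channel_labels: Sequence[str]) -> None:
        missing = [lab for lab in self.electrodes() if lab not in channel_labels]
        if missing:
            raise KeyError(f"ROI electrodes missing from recording: {missing}")


#: The 10-region scheme: prefrontal, temporal, parietal and central lobes per
#: hemisphere, plus medial parietal and occipital.
DEFAULT_ROI = ROIScheme(
    {
        "LF": ("F7", "F3", "Fp1"),
        "RF": ("F8", "F4", "Fp2"),
        "LT": ("FT7", "T7", "TP7"),
        "RT": ("FT8", "T8", "TP8"),
        "LP": ("CP3", "P7", "P3"),
        "RP": ("CP4", "P4", "P8"),
        "LC": ("FC3", "C3"),
        "RC": ("FC4", "C4"),
        "MP": ("P1", "P2", "Pz", "POz"),
        "O": ("O1", "O2", "Oz"),
    }
)


@dataclass
class Subject:
    """One participant: group label, MMSE score, and per-condition recordings."""

    subject_id: str
    group: str
    mmse: float
    recordings: dict[str, EpochedRecording] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.mmse <= 30):
            raise ValueError(f"MMSE must lie in [0, 30], got {self.mmse}")


class CohortDataset:
    """A labeled two-group cohort with ``pre``/``post`` condition recordings."""

    def __init__(self, subjects: Sequence[Subject], groups: tuple[str, str] = ("aMCI", "control")):
        self.subjects = list(subjects)
        self.groups = groups
        labels = {s.group for s in self.subjects}
        if not labels.issubset(set(groups)):
            raise ValueError(f"unknown group labels: {sorted(labels - set(groups))}")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def conditions(self) -> tuple[str, ...]:
        conds: list[str] = []
        for s in self.subjects:
            for c in s.recordings:
                if c not in conds:
                    conds.append(c)
        return tuple(conds)

    def require_conditions(self, conditions: Sequence[str]) -> None:
        """Raise if any subject lacks one of the requested conditions."""
        for s in self.subjects:
            missing = [c for c in conditions if c not in s.recordings]
            if missing:
                raise ValueError(
                    f"subject {s.subject_id!r} missing condition(s) {missing}"
                )

    def group_of(self, subject_id: str) -> str:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s.group
        raise KeyError(subject_id)


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, with the field's defaults.

    threshold_prop
        Fraction of strongest connections retained before classical graph
        analysis (proportional threshold), default 0.10.
    n_surrogates
        Number of weight-reshuffled random networks used to normalise
        clustering and path length, default 50.
    estimator
        ``"dwpli"`` (debiased squared WPLI) or ``"wpli"``.
    band_collapse
        ``"bins_then_epochs"`` collapses cross-spectra over in-band FFT bins
        before the epoch-wise estimator; ``"epochs_per_bin"`` runs the
        estimator per bin and averages after.
    clustering_variant
        ``"as_printed"`` for the plain triple-product weighted clustering
        coefficient, ``"onnela"`` for the cube-root variant.
    """

    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    roi: ROIScheme | None = DEFAULT_ROI
    channels: tuple[str, ...] | None = SCALP_60
    threshold_prop: float = 0.10
    n_surrogates: int = 50
    seed: int = 0
    fdr_q: float = 0.05
    estimator: str = "dwpli"
    band_collapse: str = "bins_then_epochs"
    clustering_variant: str = "as_printed"
    conditions: tuple[str, ...] = ("pre", "post")
    # classifier settings
    n_trees: int = 200
    rfe_step: float = 0.2
    n_select: int | str = 20
    positive_class: str = "aMCI"

    def __post_init__(self) -> None:
        if not (0 < self.threshold_prop <= 1):
            raise ValueError("threshold_prop must lie in (0, 1]")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if self.estimator not in ("dwpli", "wpli"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.band_collapse not in ("bins_then_epochs", "epochs_per_bin"):
            raise ValueError(f"unknown band_collapse {self.band_collapse!r}")
        if self.clustering_variant not in ("as_printed", "onnela"):
            raise ValueError(f"unknown clustering_variant {self.clustering_variant!r}")

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    # -- round-trip through plain dict / YAML ---------------------------------
    def to_dict(self) -> dict:
        return {
            "bands": [[b.name, b.f_lo, b.f_hi] for b in self.bands],
            "roi": {k: list(v) for k, v in self.roi.regions.items()} if self.roi else None,
            "channels": list(self.channels) if self.channels is not None else None,
            "threshold_prop": self.threshold_prop,
            "n_surrogates": self.n_surrogates,
            "seed": self.seed,
            "fdr_q": self.fdr_q,
            "estimator": self.estimator,
            "band_collapse": self.band_collapse,
            "clustering_variant": self.clustering_variant,
            "conditions": list(self.conditions),
            "n_trees": self.n_trees,
            "rfe_step": self.rfe_step,
            "n_select": self.n_select,
            "positive_class": self.positive_class,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        kwargs: dict = {}
        if "bands" in d:
            kwargs["bands"] = tuple(BandSpec(*b) for b in d.pop("bands"))
        if "roi" in d:
            roi = d.pop("roi")
            kwargs["roi"] = ROIScheme(roi) if roi is not None else None
        if "channels" in d:
            ch = d.pop("channels")
            kwargs["channels"] = tuple(ch) if ch is not None else None
        if "conditions" in d:
            kwargs["conditions"] = tuple(d.pop("conditions"))
        kwargs.update(d)
        return cls(**kwargs)
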