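"""Mission-phase taxonomy and timepoint-label handling.

A ten-timepoint longitudinal schedule is used by default: three pre-flight
draws (L-92, L-44, L-3), three flight days (FD1-FD3), the immediate
post-flight draw (R+1) and three recovery draws (R+45, R+82, R+194).
Labels are opaque strings; the Unicode minus sign variant (e.g. "L−44") is
accepted as an alias of the ASCII form ("L-44") because source tables mix
both dashes.

The coefficient-of-variation analysis does not use every timepoint: the
default per-modality mask restricts CV intervals to pre-flight, post-flight
and R+45/R+82 recovery, with the microbiome modalities additionally
including the in-flight FD2/FD3 draws.  R+194 is mapped to the recovery
phase (so it remains usable in contrasts) but is excluded from the default
CV mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "PHASES",
    "PRE_FLIGHT",
    "IN_FLIGHT",
    "POST_FLIGHT",
    "RECOVERY",
    "PhaseScheme",
    "default_scheme",
    "normalize_label",
    "assign_phases",
    "DEFAULT_TIMEPOINTS",
]

PRE_FLIGHT = "pre_flight"
IN_FLIGHT = "in_flight"
POST_FLIGHT = "post_flight"
RECOVERY = "recovery"
PHASES = (PRE_FLIGHT, IN_FLIGHT, POST_FLIGHT, RECOVERY)

# Unicode dash variants folded to ASCII '-' before lookup.
_DASHES = {"−": "-", "–": "-", "—": "-"}

#: Default schedule: (label, day offset relative to launch).  The mission
#: lasts three days; "R+k" is k days after return (return = day 3).
DEFAULT_TIMEPOINTS: tuple[tuple[str, int], ...] = (
    ("L-92", -92),
    ("L-44", -44),
    ("L-3", -3),
    ("FD1", 1),
    ("FD2", 2),
    ("FD3", 3),
    ("R+1", 4),
    ("R+45", 48),
    ("R+82", 85),
    ("R+194", 197),
)

_DEFAULT_MAPPING = {
    "L-92": PRE_FLIGHT,
    "L-44": PRE_FLIGHT,
    "L-3": PRE_FLIGHT,
    "FD1": IN_FLIGHT,
    "FD2": IN_FLIGHT,
    "FD3": IN_FLIGHT,
    "R+1": POST_FLIGHT,
    "R+45": RECOVERY,
    "R+82": RECOVERY,
    "R+194": RECOVERY,
}

_BASE_CV_LABELS = frozenset({"L-92", "L-44", "L-3", "R+1", "R+45", "R+82"})
_MICROBIOME_CV_LABELS = _BASE_CV_LABELS | {"FD2", "FD3"}

_DEFAULT_CV_MASK = {
    "microbiome_relabund": _MICROBIOME_CV_LABELS,
    "__default__": _BASE_CV_LABELS,
}


def normalize_label(label: str) -> str:
    """Fold Unicode dash variants in a timepoint label to ASCII '-'."""
    for bad, good in _DASHES.items():
        label = label.replace(bad, good)
    return label


@dataclass
class PhaseScheme:
    """Mapping of timepoint labels to mission phases plus per-modality CV masks.

    ``cv_mask`` maps a modality name (or the ``"__default__"`` key) to the set
    of timepoint labels whose samples enter CV-interval computations for that
    modality.
    """

    label_to_phase: dict[str, str]
    cv_mask: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(_DEFAULT_CV_MASK)
    )

    def __post_init__(self) -> None:
        bad = {p for p in self.label_to_phase.values() if p not in PHASES}
        if bad:
            raise ValueError(f"phases outside {PHASES}: {sorted(bad)}")
        # keys stored dash-normalized so both variants resolve
        self.label_to_phase = {
            normalize_label(k): v for k, v in self.label_to_phase.items()
        }
        self.cv_mask = {
            k: frozenset(normalize_label(x) for x in v) for k, v in self.cv_mask.items()
        }

    def phase_of(self, label: str) -> str:
        key = normalize_label(label)
        try:
            return self.label_to_phase[key]
        except KeyError:
            raise KeyError(f"timepoint label {label!r} not in phase scheme") from None

    def cv_labels(self, modality: str) -> frozenset[str]:
        """Timepoint labels entering CV intervals for ``modality``."""
        if modality in self.cv_mask:
            return self.cv_mask[modality]
        return self.cv_mask.get("__default__", frozenset(self.label_to_phase))

    def labels_in_phase(self, phase: str) -> list[str]:
        return [l for l, p in self.label_to_phase.items() if p == phase]


def default_scheme() -> PhaseScheme:
    """The ten-timepoint default mission scheme."""
    return PhaseScheme(label_to_phase=dict(_DEFAULT_MAPPING))


def assign_phases(samples: pd.DataFrame, scheme: PhaseScheme | None = None) -> pd.DataFrame:
    """Attach a ``phase`` column to a sample sheet.

    Raises a ``ValueError`` listing every unresolvable timepoint label.
    """
    scheme = scheme or default_scheme()
    labels = samples["timepoint_label"].map(normalize_label)
    unknown = sorted(set(labels) - set(scheme.label_to_phase))
    if unknown:
        raise ValueError(f"unresolvable timepoint labels: {unknown}")
    out = samples.copy()
    out["timepoint_label"] = labels
    out["phase"] = labels.map(scheme.label_to_phase)
    return out
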