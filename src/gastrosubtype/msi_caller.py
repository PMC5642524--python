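"""Microsatellite-instability calling from five mononucleotide markers.

Instability is judged per marker by comparing the tumor allele-length
profile against the matched non-tumor profile from the pentaplex PCR assay
(BAT-25, BAT-26, NR-21, NR-24, NR-27). The published rule operated on
capillary-electrophoresis traces without a stated numeric criterion; the
metric here is this module's own construction: a marker is unstable when
the tumor profile carries novel-allele mass (lengths outside the normal
support, beyond a +/-1 bp tolerance) of at least ``min_novel_fraction``, or
when its modal length shifts by more than ``max_shift_bp``.

Status follows the standard pentaplex rule: 0 unstable markers -> MSS,
exactly 1 -> MSI-L, 2 or more -> MSI-H.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .tables import MSI_MARKERS

MSI_STATUSES = ("MSS", "MSI-L", "MSI-H")


class MarkerMismatchError(ValueError):
    """Tumor and normal profiles refer to different markers."""


@dataclass(frozen=True)
class MsiParams:
    tolerance_bp: int = 1
    min_novel_fraction: float = 0.2
    max_shift_bp: int = 1


@dataclass(frozen=True)
class MarkerProfile:
    """Allele-length histogram for one marker in one sample."""

    marker_name: str
    histogram: Mapping[int, float]

    def __post_init__(self) -> None:
        if self.marker_name not in MSI_MARKERS:
            raise ValueError(f"unknown marker {self.marker_name!r}")
        if not self.histogram:
            raise ValueError("empty histogram")
        total = sum(self.histogram.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"support fractions sum to {total}, expected 1")
        if any(length <= 0 or int(length) != length for length in self.histogram):
            raise ValueError("allele lengths must be positive integers")

    @property
    def modal_length(self) -> int:
        # ties broken toward the shorter allele for determinism
        return min(self.histogram, key=lambda k: (-self.histogram[k], k))


@dataclass(frozen=True)
class MSIResult:
    per_marker_unstable: Mapping[str, bool]
    n_unstable: int
    status: str

    def __post_init__(self) -> None:
        if self.n_unstable != sum(self.per_marker_unstable.values()):
            raise ValueError("n_unstable inconsistent with flags")
        if self.status not in MSI_STATUSES:
            raise ValueError(f"invalid status {self.status!r}")


def assess_marker(
    tumor: MarkerProfile,
    normal: MarkerProfile,
    params: MsiParams = MsiParams(),
) -> bool:
    """Return True when the tumor profile is unstable relative to normal."""
    if tumor.marker_name != normal.marker_name:
        raise MarkerMismatchError(
            f"marker mismatch: {tumor.marker_name} vs {normal.marker_name}"
        )
    normal_support = [length for length, frac in normal.histogram.items() if frac > 0]
    novel_mass = sum(
        frac
        for length, frac in tumor.histogram.items()
        if frac > 0
        and min(abs(length - n) for n in normal_support) > params.tolerance_bp
    )
    if novel_mass >= params.min_novel_fraction:
        return True
    return abs(tumor.modal_length - normal.modal_length) > params.max_shift_bp


def call_msi_status(per_marker_flags: Mapping[str, bool]) -> MSIResult:
    """Aggregate five per-marker flags into an MSS/MSI-L/MSI-H call."""
    if set(per_marker_flags) != set(MSI_MARKERS):
        raise ValueError(
            f"expected flags for exactly the five markers {MSI_MARKERS}, "
            f"got {sorted(per_marker_flags)}"
        )
    n = sum(bool(v) for v in per_marker_flags.values())
    status = "MSS" if n == 0 else ("MSI-L" if n == 1 else "MSI-H")
    return MSIResult(
        per_marker_unstable=dict(per_marker_flags), n_unstable=n, status=status
    )


def call_case(
    tumor_profiles: Mapping[str, MarkerProfile],
    normal_profiles: Mapping[str, MarkerProfile],
    params: MsiParams = MsiParams(),
) -> MSIResult:
    """Assess all five markers for one case and call the MSI status."""
    flags = {
        m: assess_marker(tumor_profiles[m], normal_profiles[m], params)
        for m in MSI_MARKERS
    }
    return call_msi_status(flags)


# ---------------------------------------------------------------------------
# I/O: long-format TSV (case_id, sample, marker, allele_length, fraction)


def write_marker_profiles(
    path: str | Path,
    case_id: str,
    tumor: Mapping[str, MarkerProfile],
    normal: Mapping[str, MarkerProfile],
) -> None:
    rows = []
    for sample, profiles in (("tumor", tumor), ("normal", normal)):
        for marker in MSI_MARKERS:
            for length, frac in sorted(profiles[marker].histogram.items()):
                rows.append(
                    {"case_id": case_id, "sample": sample, "marker": marker,
                     "allele_length": length, "fraction": frac}
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_marker_profiles(
    path: str | Path,
) -> tuple[dict[str, MarkerProfile], dict[str, MarkerProfile]]:
    """Read one case's marker TSV -> (tumor profiles, normal profiles)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, MarkerProfile]] = {"tumor": {}, "normal": {}}
    for (sample, marker), grp in df.groupby(["sample", "marker"]):
        hist = {int(r.allele_length): float(r.fraction) for r in grp.itertuples()}
        out[str(sample)][str(marker)] = MarkerProfile(str(marker), hist)
    return out["tumor"], out["normal"]
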