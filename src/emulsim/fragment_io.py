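"""CE fragment-peak tables: reading, target assignment, matrix collapse.

Peak tables are the tabular export of fragment-analysis software (one row
per detected peak: sample, dye, fragment size, height, area).  Targets are
assigned by dye and size window from a :class:`TargetMap`; the published
assay never printed its amplicon sizes, so the map ships as configuration
with synthetic defaults matching the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .config import TARGETS
from .errors import ConfigError, FormatError, DataError

__all__ = ["TargetMap", "default_target_map", "read_peak_table", "write_peak_table",
           "assign_targets", "collapse_to_matrix"]

PEAK_COLUMNS = ["sample_id", "day", "condition", "cells", "dye", "size_bp", "height", "area"]


@dataclass
class TargetMap:
    """Per-target (dye, expected size, tolerance) windows.

    Within one dye the windows must be disjoint.  Records on the size-standard
    dye are never assigned to targets.
    """

    entries: Mapping[str, tuple[str, float, float]] = field(default_factory=dict)
    size_standard_dye: str = "ROX"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        by_dye: dict[str, list[tuple[float, float, str]]] = {}
        for target, (dye, size, tol) in self.entries.items():
            if size <= 0 or tol < 0:
                raise ConfigError(f"bad window for target {target!r}")
            if dye == self.size_standard_dye:
                raise ConfigError(f"target {target!r} assigned to the size-standard dye")
            by_dye.setdefault(dye, []).append((size - tol, size + tol, target))
        for dye, wins in by_dye.items():
            wins.sort()
            for (lo1, hi1, t1), (lo2, hi2, t2) in zip(wins, wins[1:]):
                if lo2 <= hi1:
                    raise ConfigError(
                        f"overlapping windows on dye {dye!r}: {t1!r} and {t2!r}"
                    )

    def entry(self, target: str) -> tuple[str, float, float]:
        try:
            return self.entries[target]
        except KeyError:
            raise ConfigError(f"target {target!r} not in target map") from None

    def assign(self, dye: str, size_bp: float) -> str:
        """Target label for a peak, or ``"unassigned"``."""
        if dye == self.size_standard_dye:
            return "size-standard"
        for target, (tdye, tsize, tol) in self.entries.items():
            if dye == tdye and abs(size_bp - tsize) <= tol:
                return target
        return "unassigned"

    @classmethod
    def from_yaml(cls, path) -> "TargetMap":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        std = data.pop("size_standard_dye", "ROX")
        entries = {}
        for target, spec in data.items():
            try:
                entries[target] = (str(spec["dye"]), float(spec["size_bp"]),
                                   float(spec.get("tolerance_bp", 1.0)))
            except (KeyError, TypeError, ValueError) as exc:
                raise ConfigError(f"bad target-map entry for {target!r}: {exc}") from exc
        return cls(entries=entries, size_standard_dye=std)


def default_target_map() -> TargetMap:
    """Synthetic default windows used by the simulator.

    hTERT splice amplicons sit on the FITC-like dye; the beta deletion
    removes 182 bp and the alpha deletion 36 bp from the full-length
    amplicon.  hTR and GAPDH amplicons are HEX-labelled.  Tolerance 1 bp.
    """
    return TargetMap(
        entries={
            "a+/b+": ("FITC", 457.0, 1.0),
            "a-/b+": ("FITC", 421.0, 1.0),
            "a+/b-": ("FITC", 275.0, 1.0),
            "a-/b-": ("FITC", 239.0, 1.0),
            "hTR": ("HEX", 185.0, 1.0),
            "GAPDH": ("HEX", 240.0, 1.0),
        }
    )


def assign_targets(peaks: pd.DataFrame, target_map: TargetMap) -> pd.DataFrame:
    """Annotate a peak table with target labels.

    Each record gets a ``target`` column (``"unassigned"`` outside every
    window, ``"size-standard"`` on the sizing dye).  Assignment depends only
    on dye and size, so it is invariant to record order.
    """
    missing = [c for c in ("sample_id", "dye", "size_bp", "area") if c not in peaks.columns]
    if missing:
        raise FormatError(f"peak table missing column(s): {', '.join(missing)}")
    out = peaks.copy()
    out["target"] = [
        target_map.assign(d, s) for d, s in zip(out["dye"], out["size_bp"])
    ]
    return out


def read_peak_table(path, target_map: TargetMap) -> pd.DataFrame:
    """Read a peak-table CSV and assign targets.

    The CSV must carry at least ``sample_id, dye, size_bp, area`` (the
    simulator also writes day, condition, cells and height).
    """
    peaks = pd.read_csv(path)
    return assign_targets(peaks, target_map)


def write_peak_table(peaks: pd.DataFrame, path) -> None:
    peaks.to_csv(path, index=False)


def collapse_to_matrix(peaks: pd.DataFrame) -> pd.DataFrame:
    """Collapse an annotated peak table to a samples x targets area matrix.

    Per (sample, target) the maximum-area peak is retained (ties broken by
    smaller fragment size — the deterministic stutter rule); missing pairs
    are zero.  Sample metadata (day, condition, cells) is carried through;
    conflicting cell counts for one sample raise :class:`DataError`.
    """
    meta_cols = [c for c in ("day", "condition", "cells") if c in peaks.columns]
    if peaks.empty:
        return pd.DataFrame(columns=meta_cols + list(TARGETS)).rename_axis("sample_id")
    if "target" not in peaks.columns:
        raise FormatError("peak table is not annotated (no 'target' column)")
    if "cells" in peaks.columns:
        ncc = peaks.groupby("sample_id")["cells"].nunique()
        bad = ncc[ncc > 1]
        if len(bad):
            raise DataError(
                f"conflicting cell counts for sample(s): {', '.join(map(str, bad.index[:5]))}"
            )
    samples = peaks["sample_id"].unique()
    meta = peaks.drop_duplicates("sample_id").set_index("sample_id")[meta_cols]
    mat = pd.DataFrame(0.0, index=pd.Index(samples, name="sample_id"), columns=list(TARGETS))
    hits = peaks[peaks["target"].isin(TARGETS)]
    if not hits.empty:
        # max area; ties on area -> smaller size_bp
        order_cols = ["area"]
        ascending = [False]
        if "size_bp" in hits.columns:
            order_cols.append("size_bp")
            ascending.append(True)
        best = (
            hits.sort_values(order_cols, ascending=ascending, kind="mergesort")
            .drop_duplicates(["sample_id", "target"])
        )
        for _, row in best.iterrows():
            mat.loc[row["sample_id"], row["target"]] = row["area"]
    out = meta.join(mat, how="right")
    out = out.loc[samples]
    return out
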