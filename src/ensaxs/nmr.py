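"""Amide chemical-shift perturbation (CSP) between two conditions.

The combined shift difference uses the standard nitrogen scaling:

    delta = sqrt( (dH)^2 + (dN / 5)^2 )   [ppm]

Residues observed in only one condition (e.g. exchange-broadened peaks) are
reported as absent, never as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SegmentAnnotation

__all__ = ["PeakList", "CspTable", "csp", "segment_summary", "read_peaklist_csv"]

N_SCALING = 5.0


@dataclass(frozen=True)
class PeakList:
    """Assigned amide peaks: residue id, dH (ppm), dN (ppm)."""

    records: pd.DataFrame  # columns: residue, dH, dN
    condition: str = ""

    def __post_init__(self) -> None:
        df = self.records
        required = {"residue", "dH", "dN"}
        if not required.issubset(df.columns):
            raise ValueError(f"peak list needs columns {sorted(required)}")
        if df["residue"].duplicated().any():
            raise ValueError("duplicate residue ids in peak list")
        if not np.all(np.isfinite(df[["dH", "dN"]].to_numpy(dtype=float))):
            raise ValueError("non-finite chemical shifts")
        object.__setattr__(self, "records", df.reset_index(drop=True))

    @classmethod
    def from_arrays(cls, residues, dH, dN, condition: str = "") -> "PeakList":
        return cls(
            pd.DataFrame({"residue": residues, "dH": dH, "dN": dN}),
            condition=condition,
        )


def read_peaklist_csv(path, condition: str = "") -> PeakList:
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    return PeakList(df[["residue", "dH", "dN"]], condition=condition or str(path))


@dataclass(frozen=True)
class CspTable:
    """Per-residue combined shift differences between two conditions."""

    table: pd.DataFrame  # columns: residue, d_dH, d_dN, delta
    missing_a: np.ndarray  # residues only in list b
    missing_b: np.ndarray  # residues only in list a


def csp(list_a: PeakList, list_b: PeakList) -> CspTable:
    """Combined CSP per residue present in both lists.

    delta = sqrt( (dH_b - dH_a)^2 + ((dN_b - dN_a)/5)^2 ); symmetric in the
    argument order. Residues missing in either list are reported as absent.
    """
    a, b = list_a.records, list_b.records
    if a.empty or b.empty:
        raise ValueError("peak lists must be nonempty")
    merged = a.merge(b, on="residue", suffixes=("_a", "_b"), how="inner")
    if merged.empty:
        raise ValueError("no common residues between the two peak lists")
    d_dH = merged["dH_b"] - merged["dH_a"]
    d_dN = merged["dN_b"] - merged["dN_a"]
    delta = np.sqrt(d_dH**2 + (d_dN / N_SCALING) ** 2)
    table = pd.DataFrame(
        {
            "residue": merged["residue"].to_numpy(),
            "d_dH": d_dH.to_numpy(),
            "d_dN": d_dN.to_numpy(),
            "delta": delta.to_numpy(),
        }
    ).sort_values("residue", ignore_index=True)
    only_a = np.setdiff1d(a["residue"], b["residue"])
    only_b = np.setdiff1d(b["residue"], a["residue"])
    return CspTable(table=table, missing_a=only_b, missing_b=only_a)


def segment_summary(
    csp_table: CspTable,
    segments: SegmentAnnotation,
    k: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-segment CSP statistics and flagged residues.

    A residue is flagged when its delta exceeds mean + k * SD over all
    residues in the table. Empty segments yield NaN stats with a warning.
    """
    t = csp_table.table
    mean_all = float(t["delta"].mean())
    sd_all = float(t["delta"].std(ddof=0))
    threshold = mean_all + k * sd_all
    rows = []
    for name in segments.names():
        a, b = segments[name]
        sub = t[(t["residue"] >= a) & (t["residue"] <= b)]
        if sub.empty:
            warnings.warn(f"segment {name!r} ({a}-{b}) has no observed residues",
                          stacklevel=2)
            rows.append({"segment": name, "start": a, "end": b, "n": 0,
                         "mean": np.nan, "max": np.nan})
            continue
        rows.append(
            {
                "segment": name,
                "start": a,
                "end": b,
                "n": int(len(sub)),
                "mean": float(sub["delta"].mean()),
                "max": float(sub["delta"].max()),
            }
        )
    flagged = t[t["delta"] > threshold].copy()
    flagged["threshold"] = threshold
    return pd.DataFrame(rows), flagged.reset_index(drop=True)
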