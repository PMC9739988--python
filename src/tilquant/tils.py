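"""The four electronic TILs variables computed from classified cell counts.

With T lymphocytes, U tumor cells and S stromal cells detected in an
analyzed tumor region of area A (mm²):

    eTILs%  = 100 * T / (T + U)        lymphocytes relative to tumor cells
    esTILs% = 100 * T / (T + S)        lymphocytes relative to stromal cells
    etTILs% = 100 * T / (total cells)  lymphocytes relative to all cells
    eaTILs  = T / A                    lymphocyte density per mm²

"Total cells" excludes IGNORE-class detections by default (they are false
detections and background, not cells); set ``include_ignore_in_total=True``
to count every detection in the etTILs% denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["TILsReport", "compute_tils_report", "aggregate_reports"]


@dataclass(frozen=True)
class TILsReport:
    """Per-region (or per-patient) TILs quantification."""

    n_tils: int
    n_tumor: int
    n_stroma: int
    n_ignore: int
    area_mm2: float
    eTILs_pct: float
    esTILs_pct: float
    etTILs_pct: float
    eaTILs_per_mm2: float
    qc_flags: tuple[str, ...] = field(default_factory=tuple)

    def to_row(self) -> dict:
        return {
            "n_tils": self.n_tils,
            "n_tumor": self.n_tumor,
            "n_stroma": self.n_stroma,
            "n_ignore": self.n_ignore,
            "area_mm2": self.area_mm2,
            "eTILs_pct": self.eTILs_pct,
            "esTILs_pct": self.esTILs_pct,
            "etTILs_pct": self.etTILs_pct,
            "eaTILs_per_mm2": self.eaTILs_per_mm2,
            "qc_flags": ";".join(self.qc_flags),
        }


def _ratio_pct(num: int, den: int, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(f"zero_denominator:{name}")
        return 0.0
    return 100.0 * num / den


def compute_tils_report(
    counts: dict[str, int],
    area_mm2: float,
    include_ignore_in_total: bool = False,
) -> TILsReport:
    """Compute the four TILs variables from per-class counts and region area.

    Parameters
    ----------
    counts : dict
        Per-class counts; keys ``IMMUNE``, ``TUMOR``, ``STROMA`` and
        optionally ``IGNORE``/``UNCLASSIFIED``. Missing keys count as zero.
    area_mm2 : float
        Analyzed tumor-region area in mm² (must be positive).

    Zero-denominator ratios are reported as 0 with a QC flag.
    """
    if area_mm2 <= 0:
        raise ValueError("area_mm2 must be positive")
    t = int(counts.get("IMMUNE", 0))
    u = int(counts.get("TUMOR", 0))
    s = int(counts.get("STROMA", 0))
    g = int(counts.get("IGNORE", 0)) + int(counts.get("UNCLASSIFIED", 0))
    if min(t, u, s, g) < 0:
        raise ValueError("counts must be non-negative")
    flags: list[str] = []
    total = t + u + s + (g if include_ignore_in_total else 0)
    return TILsReport(
        n_tils=t,
        n_tumor=u,
        n_stroma=s,
        n_ignore=g,
        area_mm2=float(area_mm2),
        eTILs_pct=_ratio_pct(t, t + u, flags, "eTILs"),
        esTILs_pct=_ratio_pct(t, t + s, flags, "esTILs"),
        etTILs_pct=_ratio_pct(t, total, flags, "etTILs"),
        eaTILs_per_mm2=t / area_mm2,
        qc_flags=tuple(flags),
    )


def aggregate_reports(
    reports: list[TILsReport],
    include_ignore_in_total: bool = False,
) -> TILsReport:
    """Pool per-region reports into one patient-level report.

    Counts and areas are summed and every variable recomputed from the pooled
    counts — ratios are never averaged across regions.
    """
    if not reports:
        raise ValueError("aggregate_reports requires at least one report")
    counts = {
        "IMMUNE": sum(r.n_tils for r in reports),
        "TUMOR": sum(r.n_tumor for r in reports),
        "STROMA": sum(r.n_stroma for r in reports),
        "IGNORE": sum(r.n_ignore for r in reports),
    }
    area = sum(r.area_mm2 for r in reports)
    return compute_tils_report(counts, area, include_ignore_in_total)
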