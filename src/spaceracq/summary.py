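"""Aggregation of acquisition events into a protospacer-analysis report.

The report mirrors the standard presentation for spacer-acquisition assays:
totals, protospacer location (which replicon), strand, PAM/integration
class, and per-clone insertion multiplicity, each with one-decimal
percentages.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .pam import PAM_CLASSES

MULTIPLICITY_BINS = ("1", "2", "3", "4+")


@dataclass(frozen=True)
class AcquisitionRecord:
    """One new spacer joined to its best protospacer hit and PAM class."""

    clone_id: str
    spacer_id: str
    spacer_seq: str
    replicon_id: str
    replicon_kind: str
    start: int
    end: int
    strand: str
    n_mismatches: int
    pam_class: str
    slip_offset: int | None
    up: str
    down: str


@dataclass
class AcquisitionSummary:
    total_spacers: int
    by_location: dict = field(default_factory=dict)  # kind -> (count, percent)
    by_strand: dict = field(default_factory=dict)  # '+'/'-' -> (count, percent)
    by_pam: dict = field(default_factory=dict)  # class -> (count, percent)
    by_multiplicity: dict = field(default_factory=dict)  # bin -> clone count
    excluded: dict = field(default_factory=dict)  # reason -> count


def percent(count: int, total: int) -> float | None:
    """Percentage rounded half-away-from-zero to one decimal.

    ``None`` (rendered "/") when the total is zero.  Half-away-from-zero
    matches the printed convention of acquisition reports; bankers'
    rounding would disagree on exact .x5 halves.
    """
    if total == 0:
        return None
    q = (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(q)


def format_percent(value: float | None, display: bool = False) -> str:
    """Render a percentage: '/' for undefined; display mode drops '.0'."""
    if value is None:
        return "/"
    if display and value == int(value):
        return str(int(value))
    return f"{value:.1f}"


def _count_map(values, keys) -> dict:
    counts = {k: 0 for k in keys}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    return counts


def summarize(
    events: list[AcquisitionRecord],
    multiplicities,
    excluded: dict | None = None,
) -> AcquisitionSummary:
    """Build the acquisition report from classified events.

    ``events`` is one row per new spacer; ``multiplicities`` is the
    per-clone insertion count (only clones with at least one insertion
    enter the multiplicity section, binned 1/2/3/4+).  Percentages are over
    the classified spacer total.
    """
    total = len(events)
    loc_counts = _count_map((e.replicon_kind for e in events), ())
    strand_counts = _count_map((e.strand for e in events), ("+", "-"))
    pam_counts = _count_map((e.pam_class for e in events), PAM_CLASSES)
    mult_counts = {b: 0 for b in MULTIPLICITY_BINS}
    for m in multiplicities:
        if m <= 0:
            continue
        mult_counts["4+" if m >= 4 else str(m)] += 1
    return AcquisitionSummary(
        total_spacers=total,
        by_location={k: (c, percent(c, total)) for k, c in sorted(loc_counts.items())},
        by_strand={k: (c, percent(c, total)) for k, c in strand_counts.items()},
        by_pam={k: (c, percent(c, total)) for k, c in pam_counts.items()},
        by_multiplicity=mult_counts,
        excluded=dict(excluded or {}),
    )


def ngg_reanalysis(events: list[AcquisitionRecord]) -> tuple[int, float | None]:
    """Downstream-NGG screen of events lacking any upstream C at -3/-2.

    Among events whose upstream -3..-1 is neither CCN, CNN, nor NCN (i.e.
    no C at either PAM position), count those carrying a 3'-NGG
    immediately downstream; the percentage is over the full event total.
    A high rate indicates spacers inverted during integration.
    """
    total = len(events)
    lacking = [
        e
        for e in events
        if len(e.up) >= 3 and e.up[-3] != "C" and e.up[-2] != "C"
    ]
    n_ngg = sum(1 for e in lacking if len(e.down) >= 3 and e.down[1:3] == "GG")
    return n_ngg, percent(n_ngg, total)


_PAM_LABELS = {
    "canonical": "5'-CCN",
    "flip": "Flip",
    "slip": "Slip",
    "mismatch": "Mismatch",
    "other": "Other",
}

_LOCATION_LABELS = {"plasmid": "Plasmid", "host": "Host genomic", "virus": "Virus"}


def render_table(summary: AcquisitionSummary) -> str:
    """Deterministic plain-text report with the fixed section order."""
    lines = [f"Total\t{summary.total_spacers}"]
    lines.append("Protospacer location")
    for kind in ("plasmid", "host", "virus"):
        if kind not in summary.by_location:
            lines.append(f"  {_LOCATION_LABELS[kind]}\t/")
            continue
        count, pct = summary.by_location[kind]
        if pct is None:
            lines.append(f"  {_LOCATION_LABELS[kind]}\t{count}")
        else:
            lines.append(
                f"  {_LOCATION_LABELS[kind]}\t{count} ({format_percent(pct, display=True)}%)"
            )
    for strand, label in (("+", "Forward strand"), ("-", "Reverse strand")):
        count, pct = summary.by_strand.get(strand, (0, None))
        if pct is None:
            lines.append(f"{label}\t/")
        else:
            lines.append(f"{label}\t{count} ({format_percent(pct, display=True)}%)")
    lines.append("PAM sequences")
    for cls in PAM_CLASSES:
        count, pct = summary.by_pam.get(cls, (0, None))
        if pct is None:
            lines.append(f"  {_PAM_LABELS[cls]}\t/")
        else:
            lines.append(
                f"  {_PAM_LABELS[cls]}\t{count} ({format_percent(pct, display=True)}%)"
            )
    lines.append("Single and multiple spacer insertion")
    for b, label in zip(MULTIPLICITY_BINS, ("Single", "Two", "Three", "Four+")):
        lines.append(f"  {label}\t{summary.by_multiplicity.get(b, 0)}")
    if summary.excluded:
        lines.append("Excluded")
        for reason in sorted(summary.excluded):
            lines.append(f"  {reason}\t{summary.excluded[reason]}")
    return "\n".join(lines) + "\n"


def summary_rows(summary: AcquisitionSummary) -> list[dict]:
    """Tidy rows (section, key, count, percent) for TSV output."""
    rows = [
        {"section": "total", "key": "total", "count": summary.total_spacers, "percent": ""}
    ]
    for section, mapping in (
        ("location", summary.by_location),
        ("strand", summary.by_strand),
        ("pam", summary.by_pam),
    ):
        for key, (count, pct) in mapping.items():
            rows.append(
                {
                    "section": section,
                    "key": key,
                    "count": count,
                    "percent": format_percent(pct),
                }
            )
    for b in MULTIPLICITY_BINS:
        rows.append(
            {
                "section": "multiplicity",
                "key": b,
                "count": summary.by_multiplicity.get(b, 0),
                "percent": "",
            }
        )
    for reason, count in sorted(summary.excluded.items()):
        rows.append(
            {"section": "excluded", "key": reason, "count": count, "percent": ""}
        )
    return rows
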