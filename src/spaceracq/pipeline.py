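"""Stage orchestration: simulate -> parse -> map -> classify -> summarize, and deg.

Two surfaces: :func:`analyze` runs the whole acquisition analysis in memory
(the path tests and simulations use); the ``run_*`` functions are the
file-based stages behind the CLI, each writing its outputs plus a
deterministic JSON manifest (package version, parameters, seed where
relevant, input checksums).  On failure a stage removes its partial
outputs.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .arrays import CRISPRLocus, ParsedClone, parse_amplicons
from .mapping import DEFAULT_PRIORITY, Replicon, map_spacer, select_best_hit
from .pam import DEFAULT_FLANK_LEN, DEFAULT_SLIP_OFFSETS, classify_pam, extract_flanks
from .summary import AcquisitionRecord, AcquisitionSummary, ngg_reanalysis, render_table, summarize, summary_rows
from .synthetic import GeneratorConfig, generate_dataset
from . import io as sqio
from .deg import call_degs, replicate_concordance

EVENT_COLUMNS = [
    "clone_id",
    "spacer_id",
    "spacer_seq",
    "replicon_id",
    "replicon_kind",
    "start",
    "end",
    "strand",
    "n_mismatches",
    "pam_class",
    "slip_offset",
    "up",
    "down",
    "status",
]


@dataclass
class AnalysisParams:
    repeat_mismatch: int = 2
    anchor_mismatch: int = 2
    map_mismatch: int = 2
    priority: tuple = DEFAULT_PRIORITY
    slip_offsets: tuple = DEFAULT_SLIP_OFFSETS
    flank_len: int = DEFAULT_FLANK_LEN


@dataclass
class AnalysisResult:
    clones: list[ParsedClone]
    events: list[AcquisitionRecord]  # classified (status 'best') events
    excluded: dict
    summary: AcquisitionSummary
    ngg: tuple  # (count, percent) of the downstream-NGG re-analysis
    all_rows: list[dict] = field(default_factory=list)  # incl. ambiguous/unmapped


def analyze(
    replicons: list[Replicon],
    locus: CRISPRLocus,
    amplicons,
    params: AnalysisParams | None = None,
) -> AnalysisResult:
    """Parse amplicons, map each new spacer, classify its PAM, summarize."""
    params = params or AnalysisParams()
    clones = parse_amplicons(
        amplicons,
        locus,
        max_mismatch=params.repeat_mismatch,
        anchor_mismatch=params.anchor_mismatch,
    )
    excluded: dict[str, int] = {}
    events: list[AcquisitionRecord] = []
    all_rows: list[dict] = []
    for clone in clones:
        if clone.status != "ok":
            excluded[f"clone_{clone.status}"] = excluded.get(f"clone_{clone.status}", 0) + 1
            continue
        for rec in clone.spacers:
            if not rec.is_new:
                continue
            spacer_id = f"{clone.clone_id}:s{rec.position_from_leader}"
            hits = map_spacer(
                rec.seq, replicons, params.map_mismatch, spacer_id=spacer_id
            )
            status, best = select_best_hit(hits, params.priority)
            row = {
                "clone_id": clone.clone_id,
                "spacer_id": spacer_id,
                "spacer_seq": rec.seq,
                "status": status,
            }
            if status != "best":
                excluded[status] = excluded.get(status, 0) + 1
                all_rows.append(row)
                continue
            rep = next(r for r in replicons if r.id == best.replicon_id)
            flanks = extract_flanks(best, rep, params.flank_len, params.flank_len)
            if flanks.edge:
                excluded["edge"] = excluded.get("edge", 0) + 1
            call = classify_pam(flanks, params.slip_offsets)
            event = AcquisitionRecord(
                clone_id=clone.clone_id,
                spacer_id=spacer_id,
                spacer_seq=rec.seq,
                replicon_id=best.replicon_id,
                replicon_kind=best.replicon_kind,
                start=best.start,
                end=best.end,
                strand=best.strand,
                n_mismatches=best.n_mismatches,
                pam_class=call.pam_class,
                slip_offset=call.slip_offset,
                up=flanks.up,
                down=flanks.down,
            )
            events.append(event)
            row.update({k: v for k, v in asdict(event).items() if k not in row})
            all_rows.append(row)
    multiplicities = [c.multiplicity for c in clones if c.status == "ok"]
    summ = summarize(events, multiplicities, excluded)
    return AnalysisResult(clones, events, excluded, summ, ngg_reanalysis(events), all_rows)


# ---------------------------------------------------------------------------
# file-based stages


def _write_manifest(outdir: Path, stage: str, params: dict, inputs: dict, outputs):
    manifest = {
        "stage": stage,
        "package": "spaceracq",
        "version": __version__,
        "params": params,
        "inputs": {Path(k).name: sqio.sha256_file(k) for k in inputs},
        "outputs": sorted(str(o) for o in outputs),
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path


def _run_stage(outdir, stage, params, inputs, writer):
    """Run ``writer() -> [output paths]``, removing partial outputs on error."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        written = [Path(p) for p in writer(outdir)]
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    _write_manifest(outdir, stage, params, inputs, [p.name for p in written])
    return written


def run_simulate(config: GeneratorConfig, outdir) -> Path:
    """Generate a dataset and write replicons/amplicons/locus/truth/config."""

    def writer(outdir: Path):
        ds = generate_dataset(config)
        paths = []
        p = outdir / "replicons.fasta"
        sqio.write_fasta([(r.id, r.seq) for r in ds.replicons], p)
        paths.append(p)
        p = outdir / "amplicons.fasta"
        sqio.write_fasta(ds.amplicons, p)
        paths.append(p)
        p = outdir / "locus.txt"
        sqio.write_locus(ds.locus, p)
        paths.append(p)
        p = outdir / "truth.tsv"
        sqio.write_truth(ds.truth, p)
        paths.append(p)
        p = outdir / "config.yaml"
        import yaml

        p.write_text(yaml.safe_dump(asdict(config), sort_keys=True))
        paths.append(p)
        return paths

    _run_stage(outdir, "simulate", asdict(config), {}, writer)
    return Path(outdir)


def run_parse(amplicons_path, locus_path, outdir, params: AnalysisParams | None = None):
    params = params or AnalysisParams()

    def writer(outdir: Path):
        locus = sqio.read_locus(locus_path)
        amplicons = sqio.read_fasta(amplicons_path)
        clones = parse_amplicons(
            amplicons,
            locus,
            max_mismatch=params.repeat_mismatch,
            anchor_mismatch=params.anchor_mismatch,
        )
        spacer_rows = [
            {
                "clone_id": rec.clone_id,
                "position_from_leader": rec.position_from_leader,
                "seq": rec.seq,
                "is_new": rec.is_new,
            }
            for clone in clones
            for rec in clone.spacers
        ]
        clone_rows = [
            {
                "clone_id": c.clone_id,
                "status": c.status,
                "multiplicity": c.multiplicity,
                "reason": c.reason,
            }
            for c in clones
        ]
        p1 = outdir / "spacers.tsv"
        sqio.write_tsv(pd.DataFrame(spacer_rows, columns=["clone_id", "position_from_leader", "seq", "is_new"]), p1)
        p2 = outdir / "clones.tsv"
        sqio.write_tsv(pd.DataFrame(clone_rows, columns=["clone_id", "status", "multiplicity", "reason"]), p2)
        return [p1, p2]

    return _run_stage(
        outdir,
        "parse",
        asdict(params),
        {amplicons_path: None, locus_path: None},
        writer,
    )


def run_map(replicons_path, spacers_path, outdir, params: AnalysisParams | None = None):
    params = params or AnalysisParams()

    def writer(outdir: Path):
        replicons = sqio.read_replicons(replicons_path)
        spacers = sqio.read_tsv(spacers_path)
        rows = []
        for _, r in spacers[spacers["is_new"]].iterrows():
            spacer_id = f"{r.clone_id}:s{r.position_from_leader}"
            hits = map_spacer(r.seq, replicons, params.map_mismatch, spacer_id=spacer_id)
            status, best = select_best_hit(hits, params.priority)
            row = {
                "clone_id": r.clone_id,
                "spacer_id": spacer_id,
                "spacer_seq": r.seq,
                "status": status,
            }
            if best is not None:
                row.update(
                    replicon_id=best.replicon_id,
                    replicon_kind=best.replicon_kind,
                    start=best.start,
                    end=best.end,
                    strand=best.strand,
                    n_mismatches=best.n_mismatches,
                )
            rows.append(row)
        cols = [
            "clone_id", "spacer_id", "spacer_seq", "replicon_id", "replicon_kind",
            "start", "end", "strand", "n_mismatches", "status",
        ]
        p = outdir / "hits.tsv"
        sqio.write_tsv(pd.DataFrame(rows, columns=cols), p)
        return [p]

    return _run_stage(
        outdir, "map", asdict(params), {replicons_path: None, spacers_path: None}, writer
    )


def run_classify(replicons_path, hits_path, outdir, params: AnalysisParams | None = None):
    params = params or AnalysisParams()

    def writer(outdir: Path):
        from .mapping import ProtospacerHit

        replicons = {r.id: r for r in sqio.read_replicons(replicons_path)}
        hits = sqio.read_tsv(hits_path)
        rows = []
        for _, r in hits.iterrows():
            row = dict(r)
            if r["status"] == "best":
                hit = ProtospacerHit(
                    spacer_id=r.spacer_id,
                    replicon_id=r.replicon_id,
                    replicon_kind=r.replicon_kind,
                    start=int(r.start),
                    end=int(r.end),
                    strand=r.strand,
                    n_mismatches=int(r.n_mismatches),
                )
                flanks = extract_flanks(
                    hit, replicons[r.replicon_id], params.flank_len, params.flank_len
                )
                call = classify_pam(flanks, params.slip_offsets)
                row.update(
                    pam_class=call.pam_class,
                    slip_offset=call.slip_offset,
                    up=flanks.up,
                    down=flanks.down,
                )
            rows.append(row)
        p = outdir / "events.tsv"
        sqio.write_tsv(pd.DataFrame(rows, columns=EVENT_COLUMNS), p)
        return [p]

    return _run_stage(
        outdir, "classify", asdict(params), {replicons_path: None, hits_path: None}, writer
    )


def run_summarize(events_path, clones_path, outdir):
    def writer(outdir: Path):
        events_df = sqio.read_tsv(events_path)
        clones = sqio.read_tsv(clones_path)
        events = [
            AcquisitionRecord(
                clone_id=r.clone_id,
                spacer_id=r.spacer_id,
                spacer_seq=r.spacer_seq,
                replicon_id=r.replicon_id,
                replicon_kind=r.replicon_kind,
                start=int(r.start),
                end=int(r.end),
                strand=r.strand,
                n_mismatches=int(r.n_mismatches),
                pam_class=r.pam_class,
                slip_offset=None if pd.isna(r.slip_offset) else int(r.slip_offset),
                up=r.up if isinstance(r.up, str) else "",
                down=r.down if isinstance(r.down, str) else "",
            )
            for _, r in events_df.iterrows()
            if r["status"] == "best"
        ]
        excluded: dict[str, int] = {}
        for status, n in events_df["status"].value_counts().items():
            if status != "best":
                excluded[status] = int(n)
        for status, n in clones["status"].value_counts().items():
            if status != "ok":
                excluded[f"clone_{status}"] = int(n)
        mult = clones.loc[clones["status"] == "ok", "multiplicity"]
        summ = summarize(events, mult.tolist(), excluded)
        n_ngg, pct_ngg = ngg_reanalysis(events)
        p1 = outdir / "summary.tsv"
        sqio.write_tsv(pd.DataFrame(summary_rows(summ)), p1)
        p2 = outdir / "summary.txt"
        text = render_table(summ)
        text += f"3'-NGG among events without upstream C at -3/-2\t{n_ngg}"
        text += "" if pct_ngg is None else f" ({pct_ngg}%)"
        p2.write_text(text + "\n")
        return [p1, p2]

    return _run_stage(
        outdir, "summarize", {}, {events_path: None, clones_path: None}, writer
    )


def run_deg(
    counts_path,
    outdir,
    sample1_cols=("count_s1r1", "count_s1r2"),
    sample2_cols=("count_s2r1", "count_s2r2"),
    **thresholds,
):
    def writer(outdir: Path):
        counts = sqio.read_counts(counts_path)
        degs = call_degs(counts, sample1_cols, sample2_cols, **thresholds)
        conc = replicate_concordance(counts, sample1_cols, sample2_cols)
        p1 = outdir / "degs.tsv"
        sqio.write_tsv(degs.round(6), p1, index=True)
        p2 = outdir / "replicate_concordance.tsv"
        sqio.write_tsv(conc.round(6), p2)
        return [p1, p2]

    return _run_stage(
        outdir,
        "deg",
        {"sample1_cols": list(sample1_cols), "sample2_cols": list(sample2_cols), **thresholds},
        {counts_path: None},
        writer,
    )


def run_all(config: GeneratorConfig, outdir, params: AnalysisParams | None = None):
    """simulate -> parse -> map -> classify -> summarize in one directory."""
    outdir = Path(outdir)
    params = params or AnalysisParams()
    run_simulate(config, outdir)
    run_parse(outdir / "amplicons.fasta", outdir / "locus.txt", outdir, params)
    run_map(outdir / "replicons.fasta", outdir / "spacers.tsv", outdir, params)
    run_classify(outdir / "replicons.fasta", outdir / "hits.tsv", outdir, params)
    run_summarize(outdir / "events.tsv", outdir / "clones.tsv", outdir)
    return outdir
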