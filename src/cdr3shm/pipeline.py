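"""End-to-end orchestration: QC -> annotate -> clonotypes -> SHM -> topology.

The per-sample flow mirrors the accounting of an amplicon AIRR-seq study:
raw pairs -> pre-merge filtered -> merged -> length/quality filtered ->
CDR3-window filtered -> productive -> truly unmutated, with every read
landing in exactly one tally per stage.  Heavy stages run on uint8
matrices; annotation operates on deduplicated sequences (clonotyping is a
dedup anyway) so cohort-scale simulations stay fast.
"""
from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import clonotypes as ct
from . import hotspots as hs
from . import qc
from . import shm
from ._seqtools import encode, unique_rows
from .annotate import annotate_batch, write_airr_tsv
from .germline import GermlineDB, default_db
from .simulate import SimulatedSample


@dataclass
class PipelineConfig:
    """All stage parameters, surfaced with the analysis' standard values."""

    min_overlap: int = 30
    max_mismatch_frac: float = 0.25
    premerge_min_mean_q: float = 25.0
    merged_min_len: int = 100
    merged_max_len: int = 350
    merged_min_mean_q: float = 25.0
    window_near: int = 30
    window_far: int = 45
    window_min_q: int = 30
    read_cutoff: int = 66
    allow_germline_exception: bool = True
    min_d_match: int = 5
    alpha: float = 0.05
    proximity: int = 2


@dataclass
class SampleResult:
    sample_id: str
    isotype: str
    qc_report: qc.QCReport
    annotated: pd.DataFrame  # unique surviving sequences + duplicate_count
    clonotypes: pd.DataFrame  # roles assigned, all productive clonotypes
    truly_unmutated: pd.DataFrame  # post-identity-filter, post-cutoff
    discarded: pd.DataFrame
    main: pd.Series | None
    events: pd.DataFrame
    topology: pd.DataFrame


class PipelineError(RuntimeError):
    pass


def _stage(name: str, sample_id: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(
                    f"stage '{name}' failed for sample '{sample_id}': {exc}"
                ) from exc

    return _Ctx()


def read_fastq_gz(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a (gzipped) Phred+33 FASTQ into uint8 sequence/quality matrices.

    Reads must be uniform-length (substitution-only amplicon data)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    seqs, quals = [], []
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            seqs.append(encode(seq))
            quals.append(np.frombuffer(qual.encode(), dtype=np.uint8) - 33)
    if not seqs:
        raise ValueError(f"no reads in {path}")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"non-uniform read lengths in {path}: {sorted(lengths)}")
    return np.stack(seqs), np.stack(quals).astype(np.uint8)


def process_sample(
    r1: np.ndarray,
    q1: np.ndarray,
    r2: np.ndarray,
    q2: np.ndarray,
    db: GermlineDB,
    config: PipelineConfig | None = None,
    sample_id: str = "sample",
    isotype: str = "IGM",
) -> SampleResult:
    """Run QC, annotation, clonotype and SHM analysis for one sample+isotype."""
    cfg = config or PipelineConfig()
    report = qc.QCReport()
    n_raw = r1.shape[0]
    report.add("raw_pairs", n_raw)

    with _stage("qc", sample_id):
        # Identical (sequence, quality) pairs are interchangeable through
        # every downstream stage, so collapse them first and carry weights;
        # on low-error repertoires this shrinks the merge workload by
        # orders of magnitude.
        stacked = np.concatenate([r1, q1, r2, q2], axis=1)
        uniq_pairs, pair_w = unique_rows(stacked)
        L0 = r1.shape[1]
        r1u, q1u = uniq_pairs[:, :L0], uniq_pairs[:, L0: 2 * L0]
        r2u, q2u = uniq_pairs[:, 2 * L0: 3 * L0], uniq_pairs[:, 3 * L0:]

        ok_pre = (
            (q1u.mean(axis=1) >= cfg.premerge_min_mean_q)
            & (q2u.mean(axis=1) >= cfg.premerge_min_mean_q)
        )
        report.add("premerge_low_mean_q", int(pair_w[~ok_pre].sum()))
        idx = np.flatnonzero(ok_pre)
        groups, _ = qc.merge_batch(
            r1u[idx], q1u[idx], r2u[idx], q2u[idx],
            min_overlap=cfg.min_overlap,
            max_mismatch_frac=cfg.max_mismatch_frac,
        )
        w = pair_w[idx]
        n_rej = int(w.sum() - sum(w[g.src_index].sum() for g in groups))
        report.add("merge_rejected", n_rej)

        surv_seqs, surv_w = [], []
        n_len, n_meanq, n_window, n_pass = 0, 0, 0, 0
        for grp in groups:
            gw = w[grp.src_index]
            L = grp.seqs.shape[1]
            if not (cfg.merged_min_len <= L <= cfg.merged_max_len):
                n_len += int(gw.sum())
                continue
            mq = grp.quals.mean(axis=1) >= cfg.merged_min_mean_q
            n_meanq += int(gw[~mq].sum())
            wok, _ = qc.cdr3_window_filter_batch(
                grp.seqs[mq], grp.quals[mq],
                window_near=cfg.window_near, window_far=cfg.window_far,
                min_q=cfg.window_min_q,
            )
            n_window += int(gw[mq][~wok].sum())
            n_pass += int(gw[mq][wok].sum())
            surv_seqs.append(grp.seqs[mq][wok])
            surv_w.append(gw[mq][wok])
        report.add("merged_bad_length", n_len)
        report.add("merged_low_mean_q", n_meanq)
        report.add("cdr3_window_fail", n_window)
        report.add("qc_passed", n_pass)

    with _stage("annotate", sample_id):
        frames = []
        for seqs, weights in zip(surv_seqs, surv_w):
            if seqs.shape[0] == 0:
                continue
            uniq, counts = unique_rows(seqs, weights)
            frames.append(
                annotate_batch(
                    uniq, db, counts=counts, isotype=isotype,
                    sample_id=sample_id, min_d_match=cfg.min_d_match,
                )
            )
        annotated = (
            pd.concat(frames, ignore_index=True)
            if frames
            else annotate_batch(np.empty((0, 1), dtype=np.uint8), db)
        )
        report.add(
            "productive_reads",
            int(annotated.loc[annotated["productive"], "duplicate_count"].sum()),
        )

    with _stage("clonotype", sample_id):
        table = ct.compute_clonotypes(annotated)
        if len(table) == 0:
            empty = table.copy()
            return SampleResult(
                sample_id, isotype, report, annotated, table, empty, empty,
                None, shm.events_to_frame([]), pd.DataFrame(),
            )
        main = ct.identify_main_variant(table)
        table = ct.find_subclonal_variants(table, main)
        truly = ct.filter_truly_unmutated(table)
        germ_aa = None
        if isinstance(main.get("germline_cdr3_ref"), str):
            from ._seqtools import translate

            germ_aa = translate(main["germline_cdr3_ref"])
        kept, discarded = ct.apply_read_cutoff(
            truly, min_reads=cfg.read_cutoff,
            allow_germline_exception=cfg.allow_germline_exception,
            germline_cdr3_aa=germ_aa, main_cdr3_aa=main.get("cdr3_aa"),
        )

    with _stage("profile", sample_id):
        subclonal = kept[kept["role"] == "subclonal"]
        main_in_table = table[table["sequence"] == main["sequence"]].iloc[0]
        events_list = shm.profile_substitutions(main_in_table, subclonal)
        events = shm.events_to_frame(events_list)
        if len(events):
            events["sample_id"] = sample_id
            events["isotype"] = isotype

    with _stage("hotspots", sample_id):
        topo = _topology_for_sample(main_in_table, events_list, cfg, sample_id, isotype)

    return SampleResult(
        sample_id, isotype, report, annotated, table, kept, discarded,
        main_in_table, events, topo,
    )


def _topology_for_sample(main, events_list, cfg, sample_id, isotype):
    if not events_list or not isinstance(main.get("germline_cdr3_ref"), str):
        return hs.topology_frame([])
    seq = main["sequence"]
    cdr3_start = seq.find(main["junction"][3:-3]) if isinstance(main.get("junction"), str) else -1
    if "cdr3_start" in main.index and not pd.isna(main["cdr3_start"]):
        cdr3_start = int(main["cdr3_start"])
    if cdr3_start < 0:
        return hs.topology_frame([])
    ref = main["germline_cdr3_ref"]
    background = seq[:cdr3_start] + ref + seq[cdr3_start + len(ref):]
    hits = hs.scan_hotspots(background)
    calls = []
    for e in events_list:
        e2 = replace(e, sample_id=sample_id, isotype=isotype)
        calls.append(
            hs.classify_mutation_topology(
                e2, background, cdr3_start, proximity=cfg.proximity, hits=hits
            )
        )
    return hs.topology_frame(calls)


def process_simulated_sample(
    sample: SimulatedSample,
    db: GermlineDB | None = None,
    config: PipelineConfig | None = None,
) -> SampleResult:
    return process_sample(
        sample.r1, sample.q1, sample.r2, sample.q2,
        db or default_db(), config,
        sample_id=sample.sample_id, isotype=sample.isotype,
    )


def cohort_analysis(
    results: list[SampleResult],
    config: PipelineConfig | None = None,
    min_samples: int = 2,
) -> dict:
    """Cohort-level reporting over per-sample results (one isotype).

    Returns recurrence table, positional-targeting statistics and the
    topology summary; samples without a CDR3 are skipped.
    """
    cfg = config or PipelineConfig()
    all_events = pd.concat(
        [r.events for r in results if len(r.events)], ignore_index=True
    ) if any(len(r.events) for r in results) else shm.events_to_frame([])
    cohort = len(results)
    recurrence = shm.recurrence_report(all_events, cohort, min_samples=min_samples)
    stats_out = None
    lengths = {
        len(r.main["cdr3_aa"]) for r in results
        if r.main is not None and isinstance(r.main.get("cdr3_aa"), str)
    }
    if len(lengths) == 1 and cohort >= 2:
        L = lengths.pop()
        freq = shm.per_sample_position_frequencies(
            all_events, L, [r.sample_id for r in results]
        )
        if (freq.to_numpy() > 0).any():
            stats_out = shm.positional_targeting_test(freq, alpha=cfg.alpha)
    topo_all = pd.concat(
        [r.topology for r in results if len(r.topology)], ignore_index=True
    ) if any(len(r.topology) for r in results) else hs.topology_frame([])
    summary = hs.topology_summary(topo_all, cohort)
    return {
        "events": all_events,
        "recurrence": recurrence,
        "positional_targeting": stats_out,
        "topology_summary": summary,
    }


def run_from_config(config: dict, outdir: str | Path, seed: int | None = None) -> dict:
    """Execute the full pipeline from a configuration mapping.

    The config either names FASTQ files per sample (``samples``) or asks for
    a simulated cohort (``simulate`` block with an ``archetype`` name and
    per-sample injections).  Writes per-sample and cohort outputs under
    ``outdir`` plus a run log with per-stage read accounting, and returns
    {"results": [...], "cohort": {...}} for programmatic use.
    """
    from .germline import ARCHETYPES, build_archetype, load_germline_db
    from .simulate import InjectionSpec, simulate_cohort, write_truth

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = config.get("germline") or {}
    if g.get("fasta"):
        db = load_germline_db(g["fasta"], g["bounds"])
    else:
        db = default_db()
    cfg = PipelineConfig(**(config.get("params") or {}))
    if seed is None:
        seed = int(config.get("seed", 0))

    inputs: list[tuple[str, str, np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    if "simulate" in config:
        sim = config["simulate"]
        arc = build_archetype(ARCHETYPES[sim.get("archetype", "subset1")], db)
        injections = {}
        isotypes = tuple(sim.get("isotypes", ["IGM"]))
        for s in sim["samples"]:
            injections[s["sample_id"]] = [
                InjectionSpec(
                    cdr3_aa_position=i["cdr3_aa_position"],
                    germline_nt=i["germline_nt"],
                    mutant_nt=i["mutant_nt"],
                    codon_offset=i["codon_offset"],
                    target_frequency=i["target_frequency"],
                    isotypes=tuple(i.get("isotypes", ["IGM"])),
                )
                for i in s.get("injections", [])
            ]
        samples = simulate_cohort(
            arc, injections,
            n_reads=int(sim.get("n_reads", 5000)),
            error_rate=float(sim.get("error_rate", 0.024)),
            seed=seed,
            isotypes=isotypes,
            read_length=int(sim.get("read_length", 300)),
        )
        if sim.get("write_fastq", False):
            for s in samples.values():
                s.write(outdir / "fastq")
        write_truth(samples, outdir)
        for (sid, iso), s in samples.items():
            inputs.append((sid, iso, s.r1, s.q1, s.r2, s.q2))
    for s in config.get("samples", []) or []:
        for path in (s["r1"], s["r2"]):
            if not Path(path).exists():
                raise PipelineError(f"missing FASTQ for sample '{s['sample_id']}': {path}")
        r1, q1 = read_fastq_gz(s["r1"])
        r2, q2 = read_fastq_gz(s["r2"])
        inputs.append((s["sample_id"], s.get("isotype", "IGM"), r1, q1, r2, q2))
    if not inputs:
        raise PipelineError("config defines no samples (neither 'simulate' nor 'samples')")

    results = []
    log = {}
    for sid, iso, r1, q1, r2, q2 in inputs:
        res = process_sample(r1, q1, r2, q2, db, cfg, sample_id=sid, isotype=iso)
        write_sample_outputs(res, outdir)
        results.append(res)
        log[f"{sid}:{iso}"] = {
            **res.qc_report.counts,
            "clonotypes": int(len(res.clonotypes)),
            "main_frequency": None if res.main is None else float(res.main["frequency"]),
            "subclonal_above_cutoff": int(
                (res.truly_unmutated["role"] == "subclonal").sum()
            ) if len(res.truly_unmutated) else 0,
        }

    mu_results = [r for r in results if r.isotype == "IGM"]
    cohort = cohort_analysis(mu_results or results, cfg)
    write_cohort_outputs(cohort, outdir)
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return {"results": results, "cohort": cohort, "log": log}


def write_sample_outputs(result: SampleResult, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"{result.sample_id}_{result.isotype}"
    write_airr_tsv(result.annotated, out / f"{tag}_rearrangements.tsv")
    result.clonotypes.drop(
        columns=["cdr3_region_map"], errors="ignore"
    ).to_csv(out / f"{tag}_clonotypes.tsv", sep="\t", index=False)
    result.events.to_csv(out / f"{tag}_events.tsv", sep="\t", index=False)
    result.topology.to_csv(out / f"{tag}_topology.tsv", sep="\t", index=False)
    pd.Series(result.qc_report.counts).to_csv(
        out / f"{tag}_qc.tsv", sep="\t", header=["count"]
    )


def write_cohort_outputs(cohort: dict, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort["recurrence"].to_csv(out / "recurrence.tsv", sep="\t", index=False)
    cohort["topology_summary"].to_csv(out / "topology_summary.tsv", sep="\t", index=False)
    stats_out = cohort["positional_targeting"]
    payload = None
    if stats_out is not None:
        payload = {
            "omnibus_p": stats_out["omnibus_p"],
            "adjusted_p": [None if np.isnan(x) else x for x in stats_out["adjusted_p"]],
            "flagged_positions": stats_out["flagged_positions"],
        }
    (out / "stats.json").write_text(json.dumps({"positional_targeting": payload}, indent=2))
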