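"""One-command orchestration: CDS+protein FASTA in, corrected dS distribution out.

Stages (each materializing an artifact under the work directory):

1. ``step0_clean``      — QC-filtered gene set (seqio)
2. ``step1_hits``       — all-vs-all similarity hits (built-in engine or
                          an externally supplied tabular file)
3. ``step2_families``   — MCL gene families
4. ``step3_alignments`` — per-family codon alignments
5. ``step4_pairwise_ds``— NG86 pairwise dS table
6. ``step5_events``     — redundancy-corrected duplication events
7. ``step6_plot``       — density curve, peaks, plots

A completed stage is skipped on re-run when its inputs and the relevant
parameters are unchanged (parameter hash + input mtime check), so an
interrupted run resumes where it stopped. Per-family work (alignment,
dS, correction) can be distributed over worker processes; the merged
output order is deterministic regardless of worker count.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

from . import __version__
from . import codon_align, dedup, mcl, ng86, peaks, seqio, similarity

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    pass


@dataclass
class RunConfig:
    cds_path: str
    pep_path: str
    out_dir: str
    tmp_dir: str
    engine: Literal["builtin", "tabular"] = "builtin"
    hits_path: str | None = None
    evalue: float = 1e-10
    inflation: float = 2.0
    min_pair_bp: int = 90
    ds_max: float = 5.0
    correction_mode: dedup.Mode = "deepest_split"
    fill_value: float = 10.0
    min_aa: int = 50
    bandwidth: float | str = "silverman"
    ds_range: tuple[float, float] = (0.0, 5.0)
    threads: int = 1
    seed: int = 0

    def validate(self) -> None:
        for name in ("cds_path", "pep_path"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise ValidationError(f"{name} does not exist: {p}")
        if self.engine == "tabular":
            if not self.hits_path or not Path(self.hits_path).is_file():
                raise ValidationError("engine=tabular requires an existing hits_path")
        elif self.engine != "builtin":
            raise ValidationError(f"unknown engine {self.engine!r}")
        if Path(self.out_dir).resolve() == Path(self.tmp_dir).resolve():
            raise ValidationError("out_dir and tmp_dir must differ")
        if self.evalue < 0 or self.inflation <= 1 or self.min_pair_bp < 0:
            raise ValidationError("parameter out of range")
        if self.ds_max <= 0 or self.threads < 1:
            raise ValidationError("parameter out of range")


@dataclass
class RunResult:
    out_dir: Path
    tmp_dir: Path
    n_genes: int
    n_hits: int
    n_families: int
    n_pairs: int
    n_events: int
    peaks: list[peaks.Peak] = field(default_factory=list)


def _params_hash(params: dict) -> str:
    return hashlib.sha256(json.dumps(params, sort_keys=True).encode()).hexdigest()[:16]


class _StageCache:
    def __init__(self, tmp_dir: Path):
        self.tmp_dir = tmp_dir

    def fresh(self, name: str, params: dict, inputs: Sequence[Path], outputs: Sequence[Path]) -> bool:
        meta_path = self.tmp_dir / f"{name}.meta.json"
        if not meta_path.is_file() or not all(p.exists() for p in outputs):
            return False
        try:
            meta = json.loads(meta_path.read_text())
        except json.JSONDecodeError:
            return False
        want = {
            "params": _params_hash(params),
            "inputs": {str(p): os.path.getmtime(p) for p in inputs},
        }
        return meta == want

    def mark(self, name: str, params: dict, inputs: Sequence[Path]) -> None:
        meta = {
            "params": _params_hash(params),
            "inputs": {str(p): os.path.getmtime(p) for p in inputs},
        }
        (self.tmp_dir / f"{name}.meta.json").write_text(json.dumps(meta, indent=1))


def _family_worker(args) -> tuple[str, list[str], list[tuple]]:
    """Align one family, compute pairwise dS, return serializable rows."""
    family_id, members, cds_map, pep_map, min_pair_bp = args
    proteins = [(m, pep_map[m]) for m in members]
    pa = codon_align.align_family(proteins)
    ca = codon_align.backtranslate(pa, cds_map)
    aln_fasta = [f">{name}\n{row}" for name, row in zip(ca.ids, ca.rows)]
    rows = []
    for pair in codon_align.extract_pairs(ca, min_bp=min_pair_bp):
        r = ng86.ng86_distance(pair)
        rows.append(
            (r.gene_a, r.gene_b, r.dS, r.dN, r.pS, r.stripped_bp, int(r.saturated))
        )
    return family_id, aln_fasta, rows


def _fmt(x: float) -> str:
    import math

    return "nan" if not math.isfinite(x) else f"{x:.6f}"


def run(cfg: RunConfig) -> RunResult:
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    tmp_dir = Path(cfg.tmp_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tmp_dir.mkdir(parents=True, exist_ok=True)
    cache = _StageCache(tmp_dir)
    cds_in = Path(cfg.cds_path)
    pep_in = Path(cfg.pep_path)

    # --- step0: QC -------------------------------------------------------
    clean_cds = tmp_dir / "step0_clean_cds.fasta"
    clean_pep = tmp_dir / "step0_clean_pep.fasta"
    qc_path = tmp_dir / "step0_qc_report.tsv"
    p0 = {"min_aa": cfg.min_aa}
    if not cache.fresh("step0", p0, [cds_in, pep_in], [clean_cds, clean_pep, qc_path]):
        logger.info("step0: QC filtering inputs")
        records, report = seqio.load_gene_records(cds_in, pep_in, min_aa=cfg.min_aa)
        seqio.write_fasta(((r.gene_id, r.cds) for r in records), clean_cds)
        seqio.write_fasta(((r.gene_id, r.protein) for r in records), clean_pep)
        qc_path.write_text(report.to_tsv())
        cache.mark("step0", p0, [cds_in, pep_in])
    else:
        logger.info("step0: cached")
    cds_entries = seqio.read_fasta(clean_cds)
    pep_entries = seqio.read_fasta(clean_pep)
    records = [
        seqio.GeneRecord(gid, cds, dict(pep_entries)[gid]) for gid, cds in cds_entries
    ]
    gene_ids = [r.gene_id for r in records]
    logger.info("step0: %d genes after QC", len(records))

    # --- step1: similarity hits -----------------------------------------
    hits_path = tmp_dir / "step1_hits.m8"
    p1 = {"engine": cfg.engine, "hits": cfg.hits_path}
    if cfg.engine == "tabular":
        hits = similarity.parse_tabular_hits(cfg.hits_path)
    else:
        if not cache.fresh("step1", p1, [clean_cds], [hits_path]):
            logger.info("step1: built-in all-vs-all similarity search")
            hits = similarity.builtin_all_vs_all(records)
            with open(hits_path, "w") as fh:
                for h in hits:
                    fh.write(
                        f"{h.query}\t{h.subject}\t{h.pct_identity:.1f}\t{h.aln_len}"
                        f"\t0\t0\t0\t0\t0\t0\t{h.evalue:.3e}\t{h.bitscore:.1f}\n"
                    )
            cache.mark("step1", p1, [clean_cds])
        else:
            logger.info("step1: cached")
        hits = similarity.parse_tabular_hits(hits_path)
    logger.info("step1: %d directional hits", len(hits))

    # --- step2: families -------------------------------------------------
    fam_path = tmp_dir / "step2_families.tsv"
    p2 = {**p1, "evalue": cfg.evalue, "inflation": cfg.inflation}
    graph_inputs = [clean_cds] if cfg.engine == "builtin" else [Path(cfg.hits_path)]
    if not cache.fresh("step2", p2, graph_inputs, [fam_path]):
        logger.info("step2: graph + MCL clustering")
        graph = similarity.build_graph(hits, evalue_cutoff=cfg.evalue, nodes=gene_ids)
        families = mcl.mcl_cluster(graph, inflation=cfg.inflation)
        mcl.write_families(families, fam_path)
        cache.mark("step2", p2, graph_inputs)
    else:
        logger.info("step2: cached")
    families = mcl.read_families(fam_path)
    logger.info("step2: %d families", len(families))

    # --- step3+4: alignments and pairwise dS ----------------------------
    aln_dir = tmp_dir / "step3_alignments"
    ds_path = tmp_dir / "step4_pairwise_ds.tsv"
    p34 = {**p2, "min_pair_bp": cfg.min_pair_bp}
    if not cache.fresh("step34", p34, [fam_path], [ds_path]):
        logger.info("step3/4: aligning families and computing pairwise dS")
        aln_dir.mkdir(exist_ok=True)
        rec_map = {r.gene_id: r for r in records}
        jobs = []
        for fam in families:
            if fam.size < 2:
                continue
            cds_map = {m: rec_map[m].cds for m in fam.members}
            pep_map = {m: rec_map[m].protein for m in fam.members}
            jobs.append((fam.family_id, fam.members, cds_map, pep_map, cfg.min_pair_bp))
        if cfg.threads > 1:
            with ProcessPoolExecutor(max_workers=cfg.threads) as pool:
                results = list(pool.map(_family_worker, jobs, chunksize=16))
        else:
            results = [_family_worker(j) for j in jobs]
        results.sort(key=lambda t: t[0])
        with open(ds_path, "w") as fh:
            fh.write("family_id\tgene_a\tgene_b\tdS\tdN\tpS\tstripped_bp\tsaturated\n")
            for family_id, aln_fasta, rows in results:
                (aln_dir / f"{family_id}.aln.fasta").write_text("\n".join(aln_fasta) + "\n")
                for ga, gb, dS, dN, pS, bp, sat in rows:
                    fh.write(
                        f"{family_id}\t{ga}\t{gb}\t{_fmt(dS)}\t{_fmt(dN)}\t{_fmt(pS)}"
                        f"\t{bp}\t{sat}\n"
                    )
        cache.mark("step34", p34, [fam_path])
    else:
        logger.info("step3/4: cached")
    pairs_by_family: dict[str, list[ng86.PairwiseDs]] = {}
    n_pairs = 0
    with open(ds_path) as fh:
        next(fh)
        for line in fh:
            fid, ga, gb, dS, dN, pS, bp, sat = line.rstrip("\n").split("\t")
            pairs_by_family.setdefault(fid, []).append(
                ng86.PairwiseDs(
                    gene_a=ga,
                    gene_b=gb,
                    S=0.0,
                    N=0.0,
                    Sd=0.0,
                    Nd=0.0,
                    pS=float(pS),
                    dS=float(dS),
                    dN=float(dN),
                    stripped_bp=int(bp),
                    saturated=bool(int(sat)),
                )
            )
            n_pairs += 1
    logger.info("step4: %d pairwise dS values", n_pairs)

    # --- step5: redundancy correction -----------------------------------
    events_path = tmp_dir / "step5_events.tsv"
    values_path = tmp_dir / "step5_ds_values.txt"
    p5 = {**p34, "ds_max": cfg.ds_max, "mode": cfg.correction_mode, "fill": cfg.fill_value}
    if not cache.fresh("step5", p5, [ds_path], [events_path, values_path]):
        logger.info("step5: dS redundancy correction (%s)", cfg.correction_mode)
        events = dedup.correct_all(
            families,
            pairs_by_family,
            mode=cfg.correction_mode,
            ds_max=cfg.ds_max,
            fill_value=cfg.fill_value,
        )
        dedup.write_events(events, events_path)
        dedup.write_ds_values(events, values_path)
        cache.mark("step5", p5, [ds_path])
    else:
        logger.info("step5: cached")
    ds_values = [float(x) for x in values_path.read_text().split()]
    logger.info("step5: %d duplication events", len(ds_values))

    # --- step6: distribution + peaks -------------------------------------
    plot_prefix = tmp_dir / "step6_plot"
    detected: list[peaks.Peak] = []
    p6 = {**p5, "bandwidth": str(cfg.bandwidth), "range": list(cfg.ds_range)}
    try:
        dist = peaks.estimate_density(
            ds_values, bandwidth=cfg.bandwidth, ds_range=cfg.ds_range
        )
        detected = peaks.find_peaks(dist)
        peaks.render(dist, detected, plot_prefix)
        cache.mark("step6", p6, [values_path])
    except ValueError as exc:
        logger.warning("step6: skipped (%s)", exc)

    # --- publish final outputs -------------------------------------------
    import shutil

    for src, dst in [
        (qc_path, out_dir / "qc_report.tsv"),
        (events_path, out_dir / "events.tsv"),
        (values_path, out_dir / "ds_values.txt"),
    ]:
        shutil.copyfile(src, dst)
    for ext in ("svg", "png"):
        src = plot_prefix.with_suffix(f".{ext}")
        if src.exists():
            shutil.copyfile(src, out_dir / f"ds_distribution.{ext}")
    for suffix in ("_peaks.tsv", "_values.tsv"):
        src = plot_prefix.parent / (plot_prefix.name + suffix)
        if src.exists():
            shutil.copyfile(src, out_dir / ("ds_distribution" + suffix))

    manifest = {
        "ksforge_version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "counts": {
            "genes": len(records),
            "hits": len(hits),
            "families": len(families),
            "pairs": n_pairs,
            "events": len(ds_values),
        },
        "peaks": [
            {"ds": p.position, "density": p.height, "prominence": p.prominence}
            for p in detected
        ],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return RunResult(
        out_dir=out_dir,
        tmp_dir=tmp_dir,
        n_genes=len(records),
        n_hits=len(hits),
        n_families=len(families),
        n_pairs=n_pairs,
        n_events=len(ds_values),
        peaks=detected,
    )
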