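"""Whole-pipeline orchestration with on-disk artifacts and resume support.

Stages run in the fixed order align -> group -> conserve -> search -> merge
-> table -> cluster, each reading its inputs from and writing its outputs to
a run directory, so any stage can be recomputed from the stored artifacts of
the stages before it.  All randomness (decoy shuffling, component splitting,
PSSM calibration) derives from the single config seed through fixed
per-stage streams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import conservation as cons
from . import evaluation as ev
from . import grouping as grp
from . import pairwise as pw
from . import search_merge as sm
from . import seqdata as sd

logger = logging.getLogger(__name__)

STAGES = ("align", "group", "conserve", "search", "merge", "table", "cluster")

_STREAMS = {"calibrate": 1, "split": 2, "pssm": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAMS[stream]]))


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters.

    Defaults are the method's published operating point: connectivity at
    e <= 0.01, groups of at most 100, clique redundancy at fractional
    Hamming 0.3, median-filter frame 50, conservation threshold 0.2, minimum
    region length 20, profile search at e <= 1e-5, merge at e < 0.01 with
    90% overlap, BLOSUM50 with gap open 10 / extend 2 for pairwise search.
    """

    evalue_connectivity: float = 0.01
    max_group: int = 100
    hamming_threshold: float = 0.3
    frame: int = 50
    conservation_threshold: float = 0.2
    min_region_length: int = 20
    search_evalue: float = 1e-5
    merge_evalue: float = 0.01
    overlap_fraction: float = 0.9
    align_matrix: str = "BLOSUM50"
    score_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 2.0
    evalue_cap: float = 10.0
    min_seq_length: int = 100
    max_seq_length: int = 10000
    calibrate_pairs: int = 100
    calibrate_length: int = 200
    pssm_decoys: int = 60
    pseudocount: float = 1.0
    threads: int = 1
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)


# ---------------------------------------------------------------------------
# Artifact (de)serialization helpers


def _profiles_to_json(profiles: list[cons.RegionProfile], path: Path) -> None:
    payload = [
        {
            "region_id": p.region_id,
            "clique_id": p.clique_id,
            "span": list(p.span),
            "counts": p.counts.tolist(),
            "member_spans": {k: list(v) for k, v in sorted(p.member_spans.items())},
        }
        for p in sorted(profiles, key=lambda p: p.region_id)
    ]
    path.write_text(json.dumps(payload, sort_keys=True) + "\n")


def _profiles_from_json(path: Path) -> list[cons.RegionProfile]:
    out = []
    for d in json.loads(path.read_text()):
        out.append(
            cons.RegionProfile(
                region_id=d["region_id"],
                clique_id=d["clique_id"],
                span=tuple(d["span"]),
                counts=np.asarray(d["counts"], dtype=float),
                member_spans={k: tuple(v) for k, v in d["member_spans"].items()},
            )
        )
    return out


def _hits_to_tsv(hits: list[sm.Hit], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("region_id\tseq_id\tevalue\tstart\tend\n")
        for h in sorted(hits, key=lambda h: (h.region_id, h.seq_id)):
            fh.write(f"{h.region_id}\t{h.seq_id}\t{h.evalue:.6g}\t{h.start}\t{h.end}\n")


def _hits_from_tsv(path: Path) -> list[sm.Hit]:
    hits = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            rid, sid, ev, start, end = line.rstrip("\n").split("\t")
            hits.append(sm.Hit(rid, sid, float(ev), int(start), int(end)))
    return hits


def _require(outdir: Path, *names: str) -> None:
    for name in names:
        if not (outdir / name).exists():
            raise FileNotFoundError(f"missing upstream artifact {name!r} in {outdir}")


def _update_manifest(outdir: Path, stage: str, counts: dict) -> None:
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {"stages": {}}
    manifest["stages"][stage] = counts
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _read_input(outdir: Path, config: PipelineConfig) -> list[sd.Sequence]:
    seqs = sd.read_fasta(outdir / "input.fasta")
    return sd.length_filter(seqs, config.min_seq_length, config.max_seq_length)


# ---------------------------------------------------------------------------
# Stages


def stage_align(outdir: Path, config: PipelineConfig) -> None:
    """Calibrate e-value statistics and run the all-against-all alignment."""
    seqs = _read_input(outdir, config)
    if len(seqs) < 2:
        raise ValueError("pipeline requires at least 2 sequences after length filtering")
    matrix = sd.load_matrix(config.align_matrix)
    params = pw.calibrate(
        seqs,
        matrix,
        config.gap_open,
        config.gap_extend,
        n_pairs=config.calibrate_pairs,
        length=config.calibrate_length,
        rng=_rng(config.seed, "calibrate"),
    )
    (outdir / "calibration.json").write_text(
        json.dumps({"lambda": params.lam, "k": params.k}, sort_keys=True) + "\n"
    )
    sim = pw.all_against_all(
        seqs,
        matrix,
        config.gap_open,
        config.gap_extend,
        params=params,
        evalue_cap=config.evalue_cap,
        threads=config.threads,
    )
    sd.write_similarity_table(sim, outdir / "similarity.tsv")
    _update_manifest(
        outdir, "align", {"sequences": len(seqs), "pairs_stored": len(sim)}
    )
    logger.info("align: %d sequences, %d stored pairs", len(seqs), len(sim))


def stage_group(outdir: Path, config: PipelineConfig) -> None:
    """Components, group splitting, maximal cliques, redundancy elimination."""
    _require(outdir, "similarity.tsv")
    seqs = _read_input(outdir, config)
    sim = sd.read_similarity_table(outdir / "similarity.tsv")
    g = pw.threshold_connectivity(
        sim, [s.id for s in seqs], config.evalue_connectivity
    )
    components, singletons = grp.connected_components(g)
    rng = _rng(config.seed, "split")
    all_cliques: list[grp.Clique] = []
    for comp in components:
        for group in grp.split_large_components(comp, config.max_group, rng):
            all_cliques.extend(grp.maximal_cliques(g, group))
    kept = grp.eliminate_redundant(all_cliques, config.hamming_threshold)
    payload = {
        "components": [sorted(c) for c in components],
        "singletons": singletons,
        "cliques": [list(c) for c in kept],
    }
    (outdir / "cliques.json").write_text(json.dumps(payload, sort_keys=True) + "\n")
    _update_manifest(
        outdir,
        "group",
        {
            "components": len(components),
            "singletons": len(singletons),
            "cliques_before_elimination": len(all_cliques),
            "cliques": len(kept),
        },
    )
    logger.info(
        "group: %d components, %d singletons, %d cliques (%d before elimination)",
        len(components), len(singletons), len(kept), len(all_cliques),
    )


def stage_conserve(outdir: Path, config: PipelineConfig) -> None:
    """Align each clique, score conservation, extract region profiles."""
    _require(outdir, "cliques.json")
    seqs = {s.id: s for s in _read_input(outdir, config)}
    cliques = json.loads((outdir / "cliques.json").read_text())["cliques"]
    matrix = sd.load_matrix(config.score_matrix)
    aln_dir = outdir / "alignments"
    if aln_dir.exists():
        shutil.rmtree(aln_dir)
    aln_dir.mkdir()
    profiles: list[cons.RegionProfile] = []
    with open(outdir / "regions.tsv", "w") as regions_fh:
        regions_fh.write("region_id\tclique_id\tseq_id\tstart\tend\n")
        for idx, member_ids in enumerate(cliques):
            clique_id = f"c{idx:04d}"
            members = [seqs[sid] for sid in member_ids]
            al = cons.progressive_msa(members, matrix, config.gap_open, config.gap_extend)
            sd.write_alignment(al, aln_dir / f"{clique_id}.afa")
            track = cons.conservation_scores(al, matrix)
            smooth = cons.median_filter(track, config.frame)
            spans = cons.extract_regions(
                smooth, config.conservation_threshold, config.min_region_length
            )
            for r, span in enumerate(spans):
                region_id = f"{clique_id}_r{r}"
                profile = cons.build_profile(al, span, clique_id, region_id)
                profiles.append(profile)
                for sid, (start, end) in sorted(profile.member_spans.items()):
                    regions_fh.write(f"{region_id}\t{clique_id}\t{sid}\t{start}\t{end}\n")
    _profiles_to_json(profiles, outdir / "profiles.json")
    _update_manifest(
        outdir, "conserve", {"cliques_aligned": len(cliques), "regions": len(profiles)}
    )
    logger.info("conserve: %d regions from %d cliques", len(profiles), len(cliques))


def stage_search(outdir: Path, config: PipelineConfig) -> None:
    """Build a PSSM per region and search it against every input sequence."""
    _require(outdir, "profiles.json")
    seqs = _read_input(outdir, config)
    profiles = _profiles_from_json(outdir / "profiles.json")
    background = sm.background_frequencies(seqs)
    rng = _rng(config.seed, "pssm")
    hits: list[sm.Hit] = []
    for profile in sorted(profiles, key=lambda p: p.region_id):
        try:
            pssm = sm.build_pssm(profile, background, config.pseudocount)
        except ValueError:
            continue
        params = sm.calibrate_pssm(
            pssm, seqs, config.gap_open, config.gap_extend,
            n_decoys=config.pssm_decoys, rng=rng,
        )
        hits.extend(
            sm.pssm_search(
                pssm, seqs, params, config.search_evalue,
                config.gap_open, config.gap_extend,
            )
        )
    _hits_to_tsv(hits, outdir / "hits.tsv")
    _update_manifest(outdir, "search", {"hits": len(hits)})
    logger.info("search: %d hits", len(hits))


def stage_merge(outdir: Path, config: PipelineConfig) -> None:
    """Merge redundant regions and remap their hits."""
    _require(outdir, "profiles.json", "hits.tsv", "calibration.json")
    profiles = _profiles_from_json(outdir / "profiles.json")
    hits = _hits_from_tsv(outdir / "hits.tsv")
    cal = json.loads((outdir / "calibration.json").read_text())
    params = pw.GumbelParams(cal["lambda"], cal["k"])
    matrix = sd.load_matrix(config.align_matrix)
    merged, id_map = sm.merge_regions(
        profiles,
        matrix,
        params,
        config.gap_open,
        config.gap_extend,
        align_threshold=config.merge_evalue,
        overlap_fraction=config.overlap_fraction,
    )
    remapped = {}
    for h in hits:
        new_id = id_map.get(h.region_id, h.region_id)
        key = (new_id, h.seq_id)
        if key not in remapped or h.evalue < remapped[key].evalue:
            remapped[key] = sm.Hit(new_id, h.seq_id, h.evalue, h.start, h.end)
    merged_hits = list(remapped.values())
    _profiles_to_json(merged, outdir / "merged_profiles.json")
    _hits_to_tsv(merged_hits, outdir / "merged_hits.tsv")
    _update_manifest(
        outdir,
        "merge",
        {"regions_before_merge": len(profiles), "regions": len(merged),
         "hits": len(merged_hits)},
    )
    logger.info("merge: %d -> %d regions", len(profiles), len(merged))


def stage_table(outdir: Path, config: PipelineConfig) -> None:
    """Assemble the binary sequence x region association table."""
    _require(outdir, "merged_hits.tsv", "merged_profiles.json")
    seqs = _read_input(outdir, config)
    hits = _hits_from_tsv(outdir / "merged_hits.tsv")
    region_ids = sorted(p.region_id for p in _profiles_from_json(outdir / "merged_profiles.json"))
    table = sm.association_table(hits, [s.id for s in seqs], region_ids)
    table.to_csv(outdir / "association.tsv", sep="\t", index_label="seq_id")
    _update_manifest(
        outdir, "table",
        {"sequences": table.shape[0], "regions": table.shape[1],
         "associations": int(table.values.sum())},
    )


def stage_cluster(outdir: Path, config: PipelineConfig) -> None:
    """Optional final clustering over the association table."""
    _require(outdir, "association.tsv")
    table = pd.read_csv(outdir / "association.tsv", sep="\t", index_col="seq_id")
    table.index = table.index.astype(str)
    clusters = sm.cluster_from_associations(table)
    with open(outdir / "clusters.tsv", "w") as fh:
        fh.write("cluster_id\tseq_id\n")
        for i, members in enumerate(clusters):
            for sid in members:
                fh.write(f"cl{i:04d}\t{sid}\n")
    _update_manifest(outdir, "cluster", {"clusters": len(clusters)})


_STAGE_FUNCS = {
    "align": stage_align,
    "group": stage_group,
    "conserve": stage_conserve,
    "search": stage_search,
    "merge": stage_merge,
    "table": stage_table,
    "cluster": stage_cluster,
}


def run_pipeline(
    fasta: str | Path, config: PipelineConfig, outdir: str | Path
) -> Path:
    """Run the full pipeline on a FASTA file, writing artifacts to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    shutil.copyfile(fasta, outdir / "input.fasta")
    config.to_json(outdir / "config.json")
    (outdir / "manifest.json").write_text(json.dumps({"stages": {}}, sort_keys=True) + "\n")
    for stage in STAGES:
        try:
            _STAGE_FUNCS[stage](outdir, config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir


def resume(stage: str, outdir: str | Path) -> Path:
    """Recompute from ``stage`` onward using the artifacts stored in ``outdir``."""
    outdir = Path(outdir)
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; stages: {', '.join(STAGES)}")
    _require(outdir, "config.json", "input.fasta")
    config = PipelineConfig.from_json(outdir / "config.json")
    for s in STAGES[STAGES.index(stage):]:
        _STAGE_FUNCS[s](outdir, config)
    return outdir


def evaluate_run(
    outdir: str | Path, reference_path: str | Path
) -> ev.EvaluationReport:
    """Score a finished run against reference region annotations.

    The reference partition is derived from the annotations the same way the
    pipeline derives clusters from the association table: sequences sharing
    a reference label fall in one reference group.
    """
    import networkx as nx

    outdir = Path(outdir)
    _require(outdir, "clusters.tsv", "merged_hits.tsv", "input.fasta")
    config = PipelineConfig.from_json(outdir / "config.json")
    seq_ids = [s.id for s in _read_input(outdir, config)]
    reference = sd.read_annotations(reference_path)

    clusters_df = pd.read_csv(outdir / "clusters.tsv", sep="\t", dtype=str)
    clusters = [
        set(sub["seq_id"]) for _, sub in clusters_df.groupby("cluster_id")
    ]
    g = nx.Graph()
    for sid in seq_ids:
        g.add_node(("s", sid))
    for a in reference:
        g.add_edge(("s", a.seq_id), ("d", a.label))
    families = []
    for comp in nx.connected_components(g):
        seqs_in = {name for kind, name in comp if kind == "s"}
        if seqs_in:
            families.append(seqs_in)

    hits = _hits_from_tsv(outdir / "merged_hits.tsv")
    predicted = [
        sd.RegionAnnotation(h.seq_id, h.start, h.end, h.region_id) for h in hits
    ]
    report = ev.evaluate(clusters, families, predicted, reference)
    (outdir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    return report
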