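"""End-to-end pipeline runner and report writers.

Ties the stages together: peptide scan -> significance -> (optional)
receptor-pair conservation -> region consensus, writing TSV/JSON reports
plus a run manifest (config, seed, package version, input checksums) so a
rerun with the same config and seed is byte-identical.

All randomness derives from one top-level seed: stage seeds are the first
31 bits of SHA-256 over ``"<seed>:<stage>"``, so stages are independent and
reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .align import AlignmentParams, global_align_free_ends
from .conservation import average_conservation, region_conservation
from .consensus import build_region_stack, consensus, position_frequency_matrix
from .scan import architecture_summary, preset_params, scan_peptides
from .seqio import REGION_LABELS, read_fasta, read_topology
from .significance import SignificanceParams


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31)."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (CLI flags mirror these fields)."""

    peptides: str
    receptors: str
    topology: str
    preset: str = "peptide-scan"
    regions: tuple[str, ...] = ("EC2", "TM2", "TM6")
    sig_params: SignificanceParams = field(default_factory=SignificanceParams)
    n_shuffles: int = 0
    seed: int = 0
    out_dir: str = "modumap_out"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "regions" in data:
            data["regions"] = tuple(data["regions"])
        return cls(**data)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def hits_frame(hits) -> pd.DataFrame:
    rows = []
    for rank, h in enumerate(hits, start=1):
        aln = h.alignment
        rows.append({
            "peptide_id": h.peptide_id, "receptor_id": h.receptor_id,
            "rank": rank, "we_score": h.we_score,
            "evalue": f"{h.evalue:.3g}" if h.evalue == h.evalue else "",
            "passes": h.passes,
            "regions": ";".join(f"{r}:{o}" for r, o in h.regions),
            "query_span": f"{aln.query_span[0]}-{aln.query_span[1]}",
            "target_span": f"{aln.target_span[0]}-{aln.target_span[1]}",
        })
    return pd.DataFrame(rows, columns=[
        "peptide_id", "receptor_id", "rank", "we_score", "evalue", "passes",
        "regions", "query_span", "target_span"])


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute scan -> conservation -> consensus; return written file map.

    Stage errors are re-raised annotated with the stage name so the CLI can
    exit non-zero with a useful message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    peptides = _stage("read-peptides", lambda: read_fasta(config.peptides))
    receptors = _stage("read-receptors", lambda: read_fasta(config.receptors))
    topologies = _stage("read-topology", lambda: read_topology(
        config.topology, {s.id: len(s) for s in receptors}))

    align_params = preset_params(config.preset)

    # scan stage: every peptide against every receptor
    def _scan():
        all_hits = []
        arch = {}
        for rec in receptors:
            topo = topologies.get(rec.id)
            if topo is None:
                raise ValueError(f"no topology for receptor {rec.id!r}")
            hits = scan_peptides(
                peptides, rec, topo,
                align_params=preset_params("peptide-scan"),
                sig_params=config.sig_params,
                n_shuffles=config.n_shuffles,
                seed=derive_seed(config.seed, f"scan:{rec.id}"))
            all_hits.extend(hits)
            summary = architecture_summary(hits, topo)
            arch[rec.id] = {
                "module_present": summary.module_present,
                "n_passing_hits": sum(1 for h in hits if h.passes),
            }
        return all_hits, arch

    hits, arch = _stage("scan", _scan)
    hits_path = out / "hits.tsv"
    hits_frame(hits).to_csv(hits_path, sep="\t", index=False)
    written["hits"] = str(hits_path)

    arch_path = out / "architecture.json"
    arch_path.write_text(json.dumps(arch, indent=2, sort_keys=True) + "\n")
    written["architecture"] = str(arch_path)

    # conservation stage over consecutive receptor pairs (reference first)
    def _conserve():
        rows = []
        pair_params = preset_params("receptor-compare")
        for a, b in zip(receptors[::2], receptors[1::2]):
            aln = global_align_free_ends(a, b, pair_params)
            rows.extend(region_conservation(aln, topologies[a.id],
                                            pair_id=f"{a.id}|{b.id}"))
        return average_conservation(rows) if rows else None

    summary = _stage("conserve", _conserve)
    if summary is not None:
        cons_path = out / "conservation.tsv"
        summary.to_frame().to_csv(cons_path, sep="\t")
        written["conservation"] = str(cons_path)

    # consensus stage over configured regions
    def _logo():
        results = {}
        pair_params = preset_params("receptor-compare")
        for region in config.regions:
            stack = build_region_stack(
                region, [(r, topologies[r.id]) for r in receptors],
                pair_params)
            pfm = position_frequency_matrix(stack)
            cons = consensus(pfm)
            results[region] = {
                "consensus": cons.consensus,
                "invariant_positions": [
                    {"position": p, "residue": r}
                    for p, r in cons.invariant_positions],
                "n_members": pfm.n_members,
            }
        return results

    logos = _stage("logo", _logo)
    cons_path = out / "consensus.json"
    cons_path.write_text(json.dumps(logos, indent=2, sort_keys=True) + "\n")
    written["consensus"] = str(cons_path)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "preset": config.preset,
        "regions": list(config.regions),
        "n_shuffles": config.n_shuffles,
        "sig_params": {
            "we_threshold": config.sig_params.we_threshold,
            "window": config.sig_params.window,
            "min_equivalents": config.sig_params.min_equivalents,
            "similarity_weight": config.sig_params.similarity_weight,
        },
        "inputs": {
            "peptides": {"path": str(config.peptides),
                         "sha256": _sha256(config.peptides)},
            "receptors": {"path": str(config.receptors),
                          "sha256": _sha256(config.receptors)},
            "topology": {"path": str(config.topology),
                         "sha256": _sha256(config.topology)},
        },
        "outputs": written,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written["manifest"] = str(manifest_path)
    return written
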