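"""Validated project bundles: a directory holding the metadata CSV,
optional FASTA/GFF3, and a JSON manifest recording column roles.

The bundle is the CLI's on-disk handoff between subcommands; it is plain
text throughout, so any file can also be opened directly by the readers
in :mod:`contigscope.ingest`.
"""

from __future__ import annotations

import json
from pathlib import Path

from .errors import ContigScopeError
from .export import export_subset
from .ingest import (
    Dataset,
    assign_roles,
    attach,
    read_annotations,
    read_fasta,
    read_metadata_table,
)
from .query import Selection

MANIFEST = "manifest.json"


def write_bundle(dataset: Dataset, outdir) -> Path:
    """Write a dataset to *outdir* as a project bundle; returns the path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    everything = Selection(frozenset(dataset.contig_ids), provenance="all")
    export_subset(dataset, everything, "csv", outdir / "metadata.csv")
    manifest = {
        "metadata": "metadata.csv",
        "roles": {c.name: c.role for c in dataset.table.columns},
    }
    if dataset.sequences is not None:
        export_subset(dataset, everything, "fasta", outdir / "contigs.fasta")
        manifest["fasta"] = "contigs.fasta"
    if dataset.annotations is not None:
        export_subset(dataset, everything, "gff", outdir / "annotations.gff")
        manifest["gff"] = "annotations.gff"
    (outdir / MANIFEST).write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return outdir


def load_bundle(bundle_dir) -> Dataset:
    """Re-read and re-validate a project bundle."""
    bundle_dir = Path(bundle_dir)
    manifest_path = bundle_dir / MANIFEST
    if not manifest_path.exists():
        raise ContigScopeError(f"not a project bundle (no {MANIFEST}): {bundle_dir}")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    table = read_metadata_table(bundle_dir / manifest["metadata"])
    explicit = {
        name: role
        for name, role in manifest.get("roles", {}).items()
        if role in ("id", "x", "y", "size", "color")
    }
    dataset = assign_roles(table, explicit)
    sequences = (
        read_fasta(bundle_dir / manifest["fasta"]) if "fasta" in manifest else None
    )
    annotations = (
        read_annotations(bundle_dir / manifest["gff"]) if "gff" in manifest else None
    )
    return attach(dataset.table, sequences, annotations)
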