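"""Seeded synthetic-assembly generator.

Emulates, at desk scale, the structure of a multi-genome environmental
assembly: several planted "genomes" with distinct GC means, log-normal
coverage and contig-length distributions, full taxonomic lineages, tiled
gene models carrying Pfam-shaped annotation tokens, plus a background of
short low-coverage contigs from many bacterial species, a handful of
unclassified contigs, and one very large, massively over-represented
contig emulating a putative mobile genetic element.

Everything is driven by a single integer seed through one PCG64 generator
(``numpy.random.default_rng``), so outputs are byte-identical across runs
and platforms. Ground truth (which genome each contig came from, which
tokens were planted where) is returned alongside the data so search,
gating and plotting can be validated against a known answer.

Planted annotation tokens are synthetic identifiers shaped like Pfam
accessions (``PF`` + 5 digits) drawn from the PF008xx range; decoy tokens
on background genes come from the disjoint PF9xxxx range, so searches for
planted tokens are unambiguous.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ContigScopeError
from .ingest import (
    AnnotationFeature,
    ContigTable,
    Dataset,
    assign_roles,
    attach,
    compute_sequence_stats,
    read_metadata_table,
)
from .query import GateRect

LINEAGE_COLUMN = "Complete lineage"

_PRODUCTS = (
    "hypothetical protein",
    "conserved hypothetical protein",
    "phage integrase",
    "phage tail fiber protein",
    "ABC transporter permease",
    "DNA methyltransferase",
    "heterodisulfide reductase subunit",
    "radical SAM protein",
)


@dataclass(frozen=True)
class GenomeModel:
    """Statistical description of one planted genome.

    ``coverage_sd`` and ``length_log_sd`` are standard deviations on the
    natural-log scale (coverage and contig length are log-normal, matching
    the heavy tails of real assemblies); ``gc_sd`` is the between-contig
    SD of the per-contig GC probability, truncated to (0, 1).
    ``planted_tokens`` lists (token, number of carrier contigs) pairs;
    each carrier receives the token once, on one of its gene models.
    """

    label: str
    lineage_text: str
    gc_mean: float
    gc_sd: float
    coverage_mean: float
    coverage_sd: float
    n_contigs: int
    length_log_mean: float = math.log(3000.0)
    length_log_sd: float = 0.3
    planted_tokens: tuple[tuple[str, int], ...] = ()

    def __post_init__(self):
        if not 0.0 < self.gc_mean < 1.0:
            raise ContigScopeError(f"{self.label}: gc_mean must be in (0, 1)")
        if self.coverage_mean <= 0:
            raise ContigScopeError(f"{self.label}: coverage_mean must be > 0")
        if self.n_contigs < 1:
            raise ContigScopeError(f"{self.label}: n_contigs must be >= 1")
        for token, n in self.planted_tokens:
            if n < 1 or n > self.n_contigs:
                raise ContigScopeError(
                    f"{self.label}: cannot plant {token} on {n} of "
                    f"{self.n_contigs} contigs"
                )


@dataclass
class GroundTruth:
    """What the generator actually planted, keyed by contig id."""

    assignment: dict[str, str] = field(default_factory=dict)
    tokens: dict[str, tuple[str, ...]] = field(default_factory=dict)
    models: list[GenomeModel] = field(default_factory=list)
    foreground_labels: list[str] = field(default_factory=list)

    @property
    def n_contigs(self) -> int:
        return len(self.assignment)

    def token_carriers(self, token: str) -> dict[str, int]:
        """contig → number of planted features carrying *token*."""
        out: dict[str, int] = {}
        for cid, toks in self.tokens.items():
            n = sum(1 for t in toks if t == token)
            if n:
                out[cid] = n
        return out

    def multi_token_contigs(self) -> list[str]:
        return [cid for cid, toks in self.tokens.items() if len(toks) >= 2]

    def to_csv(self, dest) -> None:
        from .ingest import _open_text

        handle, close = _open_text(dest, "wt")
        try:
            handle.write("contig_id,genome,planted_tokens\n")
            for cid, label in self.assignment.items():
                toks = ";".join(self.tokens.get(cid, ()))
                handle.write(f"{cid},{label},{toks}\n")
        finally:
            if close:
                handle.close()


_BASES = np.frombuffer(b"GCAT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int, gc_p: float) -> str:
    """i.i.d. bases with P(G or C) = gc_p; G/C and A/T equiprobable."""
    is_gc = rng.random(length) < gc_p
    second = rng.random(length) < 0.5
    idx = np.where(is_gc, np.where(second, 0, 1), np.where(second, 2, 3))
    return _BASES[idx].tobytes().decode("ascii")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated to (0.005, 0.995) by redraw, clipping as a
    last resort so the loop always terminates."""
    if sd == 0:
        return min(max(mean, 0.005), 0.995)
    for _ in range(100):
        v = rng.normal(mean, sd)
        if 0.005 < v < 0.995:
            return v
    return min(max(mean, 0.005), 0.995)


def _slug(label: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in label)


def generate_assembly(
    models: Sequence[GenomeModel], seed: int
) -> tuple[ContigTable, dict[str, str], list[AnnotationFeature], GroundTruth]:
    """Generate contigs, sequences, gene annotations and ground truth.

    Per contig: length ~ LogNormal, sequence i.i.d. with a per-contig GC
    probability ~ truncated Normal(gc_mean, gc_sd), coverage ~ LogNormal,
    lineage copied from the model. Gene models of 300–1500 bp are tiled
    along each contig on alternating strands; planted tokens are inserted
    as ``pfam=`` attributes on randomly chosen genes of randomly chosen
    carrier contigs. Deterministic for a fixed seed.
    """
    if not models:
        raise ContigScopeError("at least one genome model is required")
    labels = [m.label for m in models]
    if len(set(labels)) != len(labels):
        raise ContigScopeError("genome model labels must be unique")

    rng = np.random.default_rng(seed)
    truth = GroundTruth(models=list(models))
    sequences: dict[str, str] = {}
    rows: list[dict] = []
    # per-contig mutable feature skeletons: (cid, start, end, strand, attrs)
    feats_by_contig: dict[str, list[dict]] = {}

    for model in models:
        contig_ids: list[str] = []
        for i in range(model.n_contigs):
            cid = f"{_slug(model.label)}_{i + 1:03d}"
            contig_ids.append(cid)
            if model.length_log_sd > 0:
                length = int(round(rng.lognormal(model.length_log_mean,
                                                 model.length_log_sd)))
            else:
                length = int(round(math.exp(model.length_log_mean)))
            length = max(length, 200)
            gc_p = _truncated_normal(rng, model.gc_mean, model.gc_sd)
            seq = _random_sequence(rng, length, gc_p)
            sequences[cid] = seq
            if model.coverage_sd > 0:
                coverage = float(
                    rng.lognormal(math.log(model.coverage_mean), model.coverage_sd)
                )
            else:
                coverage = float(model.coverage_mean)
            feats = _tile_genes(rng, cid, length)
            feats_by_contig[cid] = feats
            rows.append(
                {
                    "contig_id": cid,
                    "length": length,
                    "coverage": round(coverage, 2),
                    "n_genes": len(feats),
                    LINEAGE_COLUMN: model.lineage_text,
                }
            )
            truth.assignment[cid] = model.label
            truth.tokens[cid] = ()

        for token, n_carriers in model.planted_tokens:
            carriers = rng.choice(
                np.array(contig_ids, dtype=object), size=n_carriers, replace=False
            )
            for cid in carriers:
                feats = feats_by_contig[cid]
                gene = feats[int(rng.integers(len(feats)))]
                gene["pfam"].append(token)
                truth.tokens[cid] = truth.tokens[cid] + (token,)

    # empirical GC from the generated sequences
    stats = compute_sequence_stats(sequences)
    for row in rows:
        gc = stats[row["contig_id"]]["gc"]
        row["gc"] = round(gc, 4) if gc is not None else ""

    table = _rows_to_table(rows)
    annotations = [
        AnnotationFeature(
            contig_id=cid,
            start=g["start"],
            end=g["end"],
            strand=g["strand"],
            ftype="CDS",
            attributes=_gene_attributes(g),
            source="contigscope_sim",
            score=".",
            phase="0",
        )
        for cid, feats in feats_by_contig.items()
        for g in feats
    ]
    return table, sequences, annotations, truth


def _tile_genes(rng: np.random.Generator, cid: str, length: int) -> list[dict]:
    """Tile 300–1500 bp gene models along the contig, alternating strands,
    separated by short intergenic gaps."""
    feats: list[dict] = []
    pos = 1 + int(rng.integers(0, 80))
    strand = "+"
    while pos + 300 - 1 <= length:
        gene_len = int(rng.integers(300, 1501))
        end = min(pos + gene_len - 1, length)
        pfams = []
        if rng.random() < 0.5:  # decoy domain, disjoint accession range
            pfams.append(f"PF9{int(rng.integers(0, 10000)):04d}")
        feats.append(
            {
                "id": f"{cid}_g{len(feats) + 1}",
                "start": pos,
                "end": end,
                "strand": strand,
                "product": _PRODUCTS[int(rng.integers(len(_PRODUCTS)))],
                "pfam": pfams,
            }
        )
        strand = "-" if strand == "+" else "+"
        pos = end + 1 + int(rng.integers(20, 120))
    if not feats:  # very short contig: one gene covering most of it
        feats.append(
            {
                "id": f"{cid}_g1",
                "start": 1,
                "end": length,
                "strand": "+",
                "product": _PRODUCTS[int(rng.integers(len(_PRODUCTS)))],
                "pfam": [],
            }
        )
    return feats


def _gene_attributes(gene: dict) -> dict[str, tuple[str, ...]]:
    attrs: dict[str, tuple[str, ...]] = {
        "ID": (gene["id"],),
        "product": (gene["product"],),
    }
    if gene["pfam"]:
        attrs["pfam"] = tuple(gene["pfam"])
    return attrs


def _rows_to_table(rows: list[dict]) -> ContigTable:
    """Serialize rows through the CSV reader so the generated table is
    exactly what ingest would produce from the written file."""
    cols = ["contig_id", "length", "gc", "coverage", "n_genes", LINEAGE_COLUMN]
    buf = io.StringIO()
    buf.write(",".join(cols) + "\n")
    for row in rows:
        rendered = []
        for c in cols:
            v = row[c]
            text = "" if v == "" else str(v)
            if "," in text or '"' in text:
                text = '"' + text.replace('"', '""') + '"'
            rendered.append(text)
        buf.write(",".join(rendered) + "\n")
    buf.seek(0)
    return read_metadata_table(buf, dialect="comma")


def gates_from_models(
    models: Sequence[GenomeModel], n_sd: float = 3.0
) -> list[GateRect]:
    """Rectangular gates at ±n_sd around each model's (GC, coverage)
    centroid; the coverage interval is symmetric on the log scale."""
    gates = []
    for m in models:
        gates.append(
            GateRect(
                label=m.label,
                gc_min=m.gc_mean - n_sd * m.gc_sd,
                gc_max=m.gc_mean + n_sd * m.gc_sd,
                cov_min=m.coverage_mean * math.exp(-n_sd * m.coverage_sd),
                cov_max=m.coverage_mean * math.exp(n_sd * m.coverage_sd),
            )
        )
    return gates


# ---------------------------------------------------------------------------
# the canned desk-scale community
# ---------------------------------------------------------------------------

#: (label, terminal lineage ranks, gc_mean, coverage_mean)
_ANME_GENOMES = (
    ("ANME-1a", "ANME-1;ANME-1a;ANME-1a archaeon SB01", 0.30, 60.0),
    ("ANME-1b", "ANME-1;ANME-1b;ANME-1b archaeon SB02", 0.38, 95.0),
    ("ANME-2a", "Methanosarcinales;ANME-2a;ANME-2a archaeon SB03", 0.46, 150.0),
    ("ANME-2b", "Methanosarcinales;ANME-2b;ANME-2b archaeon SB04", 0.54, 230.0),
    ("ANME-2c", "Methanosarcinales;ANME-2c;ANME-2c archaeon SB05", 0.62, 350.0),
    ("ANME-3", "Methanosarcinales;ANME-3;ANME-3 archaeon SB06", 0.70, 520.0),
)

#: seven synthetic methane-metabolism domain families (Pfam-shaped)
TOY_TOKENS = tuple(f"PF008{i:02d}" for i in range(1, 8))

_BG_PHYLA = (
    "Proteobacteria",
    "Bacteroidetes",
    "Actinobacteria",
    "Chloroflexi",
    "Planctomycetes",
    "Verrucomicrobia",
)


def santa_barbara_toy_models() -> list[GenomeModel]:
    """The model list behind :func:`santa_barbara_toy` (foreground genomes
    first, then the mobile element, background species, unclassified)."""
    models: list[GenomeModel] = []
    # token planting: one genome gets two heavily-planted families whose
    # carrier sets must overlap (28 + 28 > 50), guaranteeing multi-token
    # contigs; the remaining families are planted sparsely.
    planting = {
        "ANME-1a": (("PF00801", 8),),
        "ANME-1b": (("PF00802", 6),),
        "ANME-2a": (("PF00803", 28), ("PF00804", 28)),
        "ANME-2b": (("PF00805", 7),),
        "ANME-2c": (("PF00806", 6),),
        "ANME-3": (("PF00807", 5),),
    }
    for label, tail, gc, cov in _ANME_GENOMES:
        models.append(
            GenomeModel(
                label=label,
                lineage_text=f"Archaea;Euryarchaeota;Methanomicrobia;{tail}",
                gc_mean=gc,
                gc_sd=0.015,
                coverage_mean=cov,
                coverage_sd=0.12,
                n_contigs=50,
                length_log_mean=math.log(3000.0),
                length_log_sd=0.3,
                planted_tokens=planting[label],
            )
        )
    # one very large, massively over-represented contig
    models.append(
        GenomeModel(
            label="mobile_element",
            lineage_text="Bacteria;Firmicutes;Bacilli;Bacillales",
            gc_mean=0.41,
            gc_sd=0.005,
            coverage_mean=3051.0,
            coverage_sd=0.0,
            n_contigs=1,
            length_log_mean=math.log(44000.0),
            length_log_sd=0.0,
        )
    )
    # background: many bacterial species, short low-coverage contigs
    idx = 0
    for phylum in _BG_PHYLA:
        for ci in range(1, 3):
            for oi in range(1, 3):
                for gi in range(1, 4):
                    n_species = 2 if (idx % 2 == 0) else 1
                    for si in range(1, n_species + 1):
                        lineage = (
                            f"Bacteria;{phylum};{phylum}_class{ci};"
                            f"{phylum}_order{ci}{oi};{phylum}_genus{ci}{oi}{gi};"
                            f"{phylum}_genus{ci}{oi}{gi} species{si}"
                        )
                        models.append(
                            GenomeModel(
                                label=f"bg_{phylum}_{ci}{oi}{gi}s{si}",
                                lineage_text=lineage,
                                gc_mean=0.35 + 0.30 * ((idx * 7) % 11) / 10.0,
                                gc_sd=0.02,
                                coverage_mean=3.0 + (idx % 7),
                                coverage_sd=0.3,
                                n_contigs=1,
                                length_log_mean=math.log(800.0),
                                length_log_sd=0.25,
                            )
                        )
                        idx += 1
    # a few contigs with no classification at all
    models.append(
        GenomeModel(
            label="unclassified_pool",
            lineage_text="",
            gc_mean=0.50,
            gc_sd=0.04,
            coverage_mean=4.0,
            coverage_sd=0.3,
            n_contigs=8,
            length_log_mean=math.log(700.0),
            length_log_sd=0.25,
        )
    )
    return models


def santa_barbara_toy(seed: int = 1) -> tuple[Dataset, GroundTruth]:
    """Desk-scale community emulating an oil-seep metagenome's structure:
    six separated archaeal genome bins carrying planted methane-metabolism
    domain tokens, a diverse low-coverage bacterial background spanning
    six phyla and >100 species lineages, a handful of unclassified
    contigs, and one 44 kb contig at 3051× coverage."""
    models = santa_barbara_toy_models()
    table, sequences, annotations, truth = generate_assembly(models, seed)
    truth.foreground_labels = [m[0] for m in _ANME_GENOMES]
    dataset = assign_roles(
        table,
        {
            "contig_id": "id",
            "coverage": "x",
            "gc": "y",
            "length": "size",
            LINEAGE_COLUMN: "color",
        },
    )
    return attach(dataset.table, sequences, annotations), truth


def foreground_gates(truth: GroundTruth, n_sd: float = 3.0) -> list[GateRect]:
    """Gates around the foreground genomes' planted centroids."""
    fg = [m for m in truth.models if m.label in set(truth.foreground_labels)]
    return gates_from_models(fg, n_sd=n_sd)
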