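"""Bacterial enzyme annotation from tabular protein-alignment hits.

Proteins from gut-bacterial genomes are annotated with a four-digit EC by
best-hit transfer from a reference enzyme database: among hits passing
Identity > 40%, Query coverage > 80% and E-value < 1e-15 (all strict),
the single best hit per query assigns its EC.  Running the aligner itself
is out of scope — the module consumes the standard 12-column tabular hit
format with a 13th column carrying the subject's EC.

The resulting records are indexed EC -> proteins -> genomes -> taxonomy,
which is what the prediction pipeline queries after it has assigned an EC
to a molecule.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from .ec import ECLabel

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_MIN = 40.0
DEFAULT_QCOV_MIN = 80.0
DEFAULT_EVALUE_MAX = 1e-15

HIT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore", "sec"]


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    subject_ec: ECLabel
    identity: float
    query_coverage: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0 <= self.identity <= 100):
            raise ValueError(f"identity out of [0,100]: {self.identity}")
        if not (0 <= self.query_coverage <= 100):
            raise ValueError(f"query coverage out of [0,100]: {self.query_coverage}")
        if self.evalue < 0:
            raise ValueError(f"negative evalue: {self.evalue}")


@dataclass(frozen=True)
class EnzymeRecord:
    protein_id: str
    genome_id: str
    taxonomy: tuple[str, ...]
    ec: ECLabel
    source_hit: AlignmentHit


@dataclass
class EnzymeDB:
    records: list[EnzymeRecord]
    ec_index: dict[str, list[int]] = field(default_factory=dict)
    genome_index: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ec_index:
            for i, rec in enumerate(self.records):
                self.ec_index.setdefault(str(rec.ec), []).append(i)
                self.genome_index.setdefault(rec.genome_id, rec.taxonomy)

    def __len__(self) -> int:
        return len(self.records)

    # -- serialization -----------------------------------------------------
    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        rows = []
        for rec in self.records:
            h = rec.source_hit
            rows.append({
                "protein_id": rec.protein_id, "genome_id": rec.genome_id,
                "taxonomy": "; ".join(rec.taxonomy), "ec": str(rec.ec),
                "subject_id": h.subject_id, "identity": h.identity,
                "query_coverage": h.query_coverage, "evalue": h.evalue,
                "bitscore": h.bitscore,
            })
        pd.DataFrame(rows).to_csv(os.path.join(directory, "enzymes.tsv"),
                                  sep="\t", index=False)
        with open(os.path.join(directory, "ec_index.json"), "w", encoding="utf-8") as fh:
            json.dump({k: v for k, v in sorted(self.ec_index.items())}, fh,
                      indent=1, sort_keys=True)

    @classmethod
    def load(cls, directory: str) -> "EnzymeDB":
        df = pd.read_csv(os.path.join(directory, "enzymes.tsv"), sep="\t", dtype=str)
        records = []
        for _, r in df.iterrows():
            ec = ECLabel.parse(r["ec"])
            hit = AlignmentHit(r["protein_id"], r["subject_id"], ec,
                               float(r["identity"]), float(r["query_coverage"]),
                               float(r["evalue"]), float(r["bitscore"]))
            records.append(EnzymeRecord(r["protein_id"], r["genome_id"],
                                        tuple(r["taxonomy"].split("; ")), ec, hit))
        return cls(records=records)


# --------------------------------------------------------------------------
# hit parsing and best-hit filtering
# --------------------------------------------------------------------------

def read_hits(path: str, query_lengths: dict[str, int] | None = None) -> list[AlignmentHit]:
    """Parse 13-column tabular hits (standard 12 columns + subject EC).

    Query coverage is taken from alignment length over query length when
    ``query_lengths`` is supplied; otherwise the alignment span on the
    query (qend - qstart + 1) is interpreted against the recorded length
    column — in that degenerate case the 'length' column must itself be
    the query length.  Most callers pass ``query_lengths``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", names=HIT_COLUMNS, dtype=str)
    hits = []
    for _, r in df.iterrows():
        qlen = query_lengths.get(r["qseqid"]) if query_lengths else None
        aln_len = float(r["length"])
        qcov = 100.0 * aln_len / qlen if qlen else min(100.0, aln_len)
        hits.append(AlignmentHit(
            query_id=r["qseqid"], subject_id=r["sseqid"],
            subject_ec=ECLabel.parse(r["sec"]),
            identity=float(r["pident"]), query_coverage=qcov,
            evalue=float(r["evalue"]), bitscore=float(r["bitscore"])))
    return hits


def filter_best_hits(
    hits: list[AlignmentHit],
    id_min: float = DEFAULT_IDENTITY_MIN,
    qcov_min: float = DEFAULT_QCOV_MIN,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> dict[str, AlignmentHit]:
    """Per-query best hit among hits passing all three strict cutoffs.

    Eligibility is identity > id_min AND query_coverage > qcov_min AND
    evalue < evalue_max (boundary values rejected).  The best eligible hit
    has the highest bitscore; ties break by lowest evalue, then
    lexicographic subject id.  Queries with no eligible hit are absent.
    """
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        if not (hit.identity > id_min and hit.query_coverage > qcov_min
                and hit.evalue < evalue_max):
            continue
        cur = best.get(hit.query_id)
        if cur is None or (-hit.bitscore, hit.evalue, hit.subject_id) < \
                (-cur.bitscore, cur.evalue, cur.subject_id):
            best[hit.query_id] = hit
    return best


def build_enzyme_db(
    best_hits: dict[str, AlignmentHit],
    protein_to_genome: dict[str, str],
    genome_taxonomy: dict[str, tuple[str, ...] | str],
) -> tuple[EnzymeDB, list[str]]:
    """Join best hits with genome membership and taxonomy.

    Proteins without a genome mapping (or genomes without taxonomy) are
    skipped and reported in the returned error list.
    """
    records, errors = [], []
    for query_id in sorted(best_hits):
        hit = best_hits[query_id]
        genome = protein_to_genome.get(query_id)
        if genome is None:
            errors.append(f"protein {query_id!r}: no genome mapping")
            continue
        tax = genome_taxonomy.get(genome)
        if tax is None:
            errors.append(f"genome {genome!r}: no taxonomy")
            continue
        if isinstance(tax, str):
            tax = tuple(t.strip() for t in tax.split(";"))
        records.append(EnzymeRecord(protein_id=query_id, genome_id=genome,
                                    taxonomy=tuple(tax), ec=hit.subject_ec,
                                    source_hit=hit))
    return EnzymeDB(records=records), errors


def lookup_ec(db: EnzymeDB, ec: ECLabel, allow_partial: bool = False) -> list[EnzymeRecord]:
    """All enzyme records carrying ``ec``.

    With ``allow_partial`` a record matches when its EC agrees on every
    non-wild level of the query (so 1.14.-.- retrieves 1.14.13.7).
    """
    if not allow_partial:
        return [db.records[i] for i in db.ec_index.get(str(ec), [])]
    return [rec for rec in db.records if ec.matches(rec.ec)]
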