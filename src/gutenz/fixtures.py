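"""Deterministic synthetic data with known ground truth.

Every stage of the method is testable without downloads: molecules are
generated from a curated scaffold library in which each (EC class, EC
subclass) pair is anchored by a distinct ring/heteroatom core decorated
with seeded substituents, so fingerprint families see class-separable
substructure patterns.  The generator plants, and records in its ground
truth, exactly the artefacts the curation filters exist to remove:
cofactor rows (from the packaged exclusion list), rows tagged with ECs
from several classes, and structural duplicates of earlier rows.  On the
enzyme side, toy genomes carry proteins with planted ECs and an
alignment-hit table containing rows on both sides of (and exactly on)
the identity/coverage/E-value cutoffs.

What this emulates: label structure, class imbalance, redundancy and the
filter boundaries.  What it does not: real chemical diversity within an
EC class, so accuracy on these fixtures bounds implementation
correctness, not real-world predictivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fingerprints
from .chem_io import from_smiles
from .substrate_db import DEFAULT_REDUNDANCY_FAMILY, load_default_cofactors

MAX_ATTEMPTS = 400

#: (class, subclass) -> SMILES template with two substituent slots.  Cores
#: differ between classes by ring system/heteroatoms and within a class by
#: functionalization, so class separation dominates subclass separation.
SCAFFOLDS: dict[tuple[int, int], str] = {
    (1, 1): "O=Cc1ccc({0})c({1})c1",
    (1, 2): "OCc1ccc({0})c({1})c1",
    (1, 3): "OC(=O)c1ccc({0})c({1})c1",
    (2, 1): "NCc1cc({0})nc({1})c1",
    (2, 2): "OCC(O)c1cc({0})nc({1})c1",
    (2, 3): "O=P(O)(O)OCc1cc({0})nc({1})c1",
    (3, 1): "O=C(O)Cc1cc({0})c({1})o1",
    (3, 2): "NC(=O)c1cc({0})c({1})o1",
    (3, 3): "OCC1OC(O)C({0})C1({1})",
    (4, 1): "OC(=O)c1cc({0})c({1})s1",
    (4, 2): "NCc1cc({0})c({1})s1",
    (4, 3): "CC(=O)c1cc({0})c({1})s1",
    (5, 1): "Oc1cc({0})nc({1})n1",
    (5, 2): "Nc1cc({0})nc({1})n1",
    (5, 3): "Cc1nc({0})cc({1})n1",
    (6, 1): "O=C(O)C1CCC({0})C({1})C1",
    (6, 2): "NC1CCC({0})C({1})C1",
    (6, 3): "OC1CCC({0})C({1})C1",
}

#: Carbon-led substituents, attachable to any ring or chain atom.
SUBSTITUENTS = ["C", "CC", "CCC", "C(C)C", "CO", "CN", "CCl", "CF",
                "CBr", "C=C", "CC=O", "CCO", "COC", "CC#N"]

#: Toy gut-bacterial genomes with full lineages.
GENOMES = {
    "g01": "Bacteria; Bacteroidetes; Bacteroidia; Bacteroidales; Bacteroidaceae; Bacteroides; Bacteroides fragilis",
    "g02": "Bacteria; Bacteroidetes; Bacteroidia; Bacteroidales; Bacteroidaceae; Bacteroides; Bacteroides thetaiotaomicron",
    "g03": "Bacteria; Firmicutes; Clostridia; Clostridiales; Lachnospiraceae; Blautia; Blautia obeum",
    "g04": "Bacteria; Firmicutes; Bacilli; Lactobacillales; Lactobacillaceae; Lactobacillus; Lactobacillus gasseri",
    "g05": "Bacteria; Proteobacteria; Gammaproteobacteria; Enterobacterales; Enterobacteriaceae; Escherichia; Escherichia coli",
    "g06": "Bacteria; Actinobacteria; Actinomycetia; Bifidobacteriales; Bifidobacteriaceae; Bifidobacterium; Bifidobacterium longum",
}

#: Mirrors the strongly skewed class distribution of real substrate sets
#: (the two largest classes near two thirds of records, the two smallest
#: near 7%); used by imbalance_profile="skewed".
SKEWED_CLASS_WEIGHTS = {1: 0.36, 2: 0.30, 3: 0.17, 4: 0.10, 5: 0.04, 6: 0.03}


@dataclass
class FixtureSpec:
    n_classes: int = 6
    subclasses_per_class: int = 3
    molecules_per_subclass: int = 20
    imbalance_profile: str = "uniform"  # uniform | skewed
    duplicate_rate: float = 0.05
    multiclass_rate: float = 0.03
    cofactor_count: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_classes <= 6:
            raise ValueError("n_classes must be 1..6")
        if not 1 <= self.subclasses_per_class <= 3:
            raise ValueError("subclasses_per_class must be 1..3")
        if min(self.molecules_per_subclass, self.cofactor_count) < 0 or \
                min(self.duplicate_rate, self.multiclass_rate) < 0:
            raise ValueError("counts and rates must be non-negative")


def preset(name: str, seed: int = 0) -> FixtureSpec:
    if name == "separable6":
        return FixtureSpec(seed=seed)
    if name == "imbalanced6":
        return FixtureSpec(imbalance_profile="skewed", seed=seed)
    raise KeyError(f"unknown preset {name!r}; available: separable6, imbalanced6")


@dataclass
class SubstrateGroundTruth:
    base_ids: list[str]
    ec_of: dict[str, list[str]]
    class_of: dict[str, int]
    subclass_of: dict[str, int]
    survivor_ids: list[str]
    cofactor_ids: list[str]
    multiclass_ids: list[str]
    duplicate_map: dict[str, str]  # duplicate id -> parent id


def _subclass_sizes(spec: FixtureSpec) -> dict[tuple[int, int], int]:
    pairs = [(c, s) for c in range(1, spec.n_classes + 1)
             for s in range(1, spec.subclasses_per_class + 1)]
    if spec.imbalance_profile == "uniform":
        return {p: spec.molecules_per_subclass for p in pairs}
    if spec.imbalance_profile != "skewed":
        raise ValueError(f"unknown imbalance profile {spec.imbalance_profile!r}")
    total = len(pairs) * spec.molecules_per_subclass
    weights = {c: SKEWED_CLASS_WEIGHTS[c] for c in range(1, spec.n_classes + 1)}
    norm = sum(weights.values())
    sizes: dict[tuple[int, int], int] = {}
    for c in range(1, spec.n_classes + 1):
        n_class = max(2 * spec.subclasses_per_class,
                      int(round(total * weights[c] / norm)))
        per = n_class // spec.subclasses_per_class
        rem = n_class - per * spec.subclasses_per_class
        for s in range(1, spec.subclasses_per_class + 1):
            sizes[(c, s)] = per + (1 if s <= rem else 0)
    return sizes


def _tc(bits_a: np.ndarray, bits_b: np.ndarray) -> float:
    inter = int(np.bitwise_and(bits_a, bits_b).sum())
    union = int(bits_a.sum()) + int(bits_b.sum()) - inter
    return inter / union if union else 0.0


def generate_substrates(spec: FixtureSpec) -> tuple[pd.DataFrame, SubstrateGroundTruth]:
    """Raw substrate table (smiles, id, ec_list) plus its ground truth.

    Base molecules are mutually non-redundant under the default
    redundancy fingerprint (pairwise TC ≤ 0.95, enforced by rejection
    sampling), so default curation retains exactly the base set: planted
    duplicates collapse onto their parents, multi-class and cofactor rows
    are filtered, nothing else moves.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _subclass_sizes(spec)
    rows: list[dict] = []
    base_ids: list[str] = []
    ec_of: dict[str, list[str]] = {}
    class_of: dict[str, int] = {}
    subclass_of: dict[str, int] = {}
    accepted_bits: list[np.ndarray] = []
    accepted_keys: set[str] = set()
    base_records: list[tuple[str, str, int, int]] = []  # id, smiles, c, s

    def decorate(c: int, s: int) -> tuple[str, str, np.ndarray]:
        template = SCAFFOLDS[(c, s)]
        for _ in range(MAX_ATTEMPTS):
            subs = rng.choice(len(SUBSTITUENTS), size=2, replace=True)
            smiles = template.format(SUBSTITUENTS[subs[0]], SUBSTITUENTS[subs[1]])
            mol = from_smiles(smiles, "probe")
            if mol.canonical_key in accepted_keys:
                continue
            bits = fingerprints.compute_fingerprint(
                mol, DEFAULT_REDUNDANCY_FAMILY).bits
            if any(_tc(bits, b) > 0.95 for b in accepted_bits):
                continue
            return smiles, mol.canonical_key, bits
        raise ValueError(f"cannot place a non-redundant molecule for EC {c}.{s} "
                         f"after {MAX_ATTEMPTS} attempts; spec infeasible")

    for (c, s), n in sizes.items():
        for i in range(n):
            smiles, key, bits = decorate(c, s)
            mol_id = f"m_{c}_{s}_{i:03d}"
            serial = 1 + i % 2  # two 4-digit ECs per subclass
            ec = f"{c}.{s}.1.{serial}"
            rows.append({"smiles": smiles, "id": mol_id, "ec_list": ec})
            base_ids.append(mol_id)
            ec_of[mol_id] = [ec]
            class_of[mol_id] = c
            subclass_of[mol_id] = s
            accepted_keys.add(key)
            accepted_bits.append(bits)
            base_records.append((mol_id, smiles, c, s))

    # planted structural duplicates (same structure, new id, same EC)
    n_dup = int(round(spec.duplicate_rate * len(base_ids)))
    duplicate_map: dict[str, str] = {}
    if n_dup:
        parents = rng.choice(len(base_records), size=n_dup, replace=False)
        for j, pi in enumerate(sorted(parents)):
            pid, psmiles, _c, _s = base_records[pi]
            did = f"dup_{j:03d}"
            duplicate_map[did] = pid
            rows.append({"smiles": psmiles, "id": did,
                         "ec_list": ";".join(ec_of[pid])})

    # planted multi-class rows (tags from two different EC classes)
    multiclass_ids: list[str] = []
    n_mc = int(round(spec.multiclass_rate * len(base_ids)))
    if n_mc and spec.n_classes >= 2:
        for j in range(n_mc):
            c1, c2 = rng.choice(np.arange(1, spec.n_classes + 1), size=2,
                                replace=False)
            s1 = int(rng.integers(1, spec.subclasses_per_class + 1))
            s2 = int(rng.integers(1, spec.subclasses_per_class + 1))
            smiles, _key, _bits = decorate(int(c1), s1)
            mid = f"mc_{j:03d}"
            multiclass_ids.append(mid)
            rows.append({"smiles": smiles, "id": mid,
                         "ec_list": f"{int(c1)}.{s1}.1.1;{int(c2)}.{s2}.1.1"})

    # planted cofactor rows
    cofactor_ids: list[str] = []
    cof_keys = sorted(load_default_cofactors())
    for j in range(min(spec.cofactor_count, len(cof_keys))):
        cid = f"cof_{j:03d}"
        cofactor_ids.append(cid)
        c = 1 + j % spec.n_classes
        rows.append({"smiles": cof_keys[j], "id": cid, "ec_list": f"{c}.1.1.1"})

    table = pd.DataFrame(rows, columns=["smiles", "id", "ec_list"])
    truth = SubstrateGroundTruth(
        base_ids=base_ids, ec_of=ec_of, class_of=class_of,
        subclass_of=subclass_of, survivor_ids=list(base_ids),
        cofactor_ids=cofactor_ids, multiclass_ids=multiclass_ids,
        duplicate_map=duplicate_map)
    return table, truth


# --------------------------------------------------------------------------
# enzyme world
# --------------------------------------------------------------------------

@dataclass
class EnzymeWorld:
    hits: pd.DataFrame              # 13-column tabular hit dialect
    query_lengths: dict[str, int]
    protein_to_genome: dict[str, str]
    genome_taxonomy: dict[str, str]
    expected_best: dict[str, str]   # query id -> winning subject id
    ec_to_genomes: dict[str, set]   # planted EC -> genomes carrying it
    boundary_queries: list[str] = field(default_factory=list)


def generate_enzyme_world(spec: FixtureSpec) -> EnzymeWorld:
    """Toy proteome + alignment-hit table with known survivors.

    Each planted EC (the ECs used by :func:`generate_substrates` under the
    same spec) gets one to three proteins spread over the toy genomes.
    Every planted protein has a clear winning hit plus a weaker eligible
    hit; additional rows fail exactly one cutoff, including rows at
    identity = 40, coverage = 80 and E-value = 1e-15 precisely, which the
    strict inequalities must reject.
    """
    rng = np.random.default_rng(spec.seed + 1)
    genome_ids = sorted(GENOMES)
    ecs = [f"{c}.{s}.1.{n}" for c in range(1, spec.n_classes + 1)
           for s in range(1, spec.subclasses_per_class + 1) for n in (1, 2)]
    rows: list[dict] = []
    qlens: dict[str, int] = {}
    p2g: dict[str, str] = {}
    expected: dict[str, str] = {}
    ec_to_genomes: dict[str, set] = {}

    def add_row(q, s, ident, length, evalue, bits, ec):
        rows.append({"qseqid": q, "sseqid": s, "pident": ident, "length": length,
                     "mismatch": 0, "gapopen": 0, "qstart": 1, "qend": length,
                     "sstart": 1, "send": length, "evalue": evalue,
                     "bitscore": bits, "sec": ec})

    pnum = 0
    for ec in ecs:
        n_prot = int(rng.integers(1, 4))
        carriers = rng.choice(len(genome_ids), size=n_prot, replace=False)
        ec_to_genomes[ec] = {genome_ids[i] for i in carriers}
        for gi in carriers:
            pid = f"p{pnum:04d}"
            pnum += 1
            p2g[pid] = genome_ids[gi]
            qlens[pid] = 100
            ref = f"ref_{ec.replace('.', '_')}"
            ident = float(np.round(rng.uniform(55, 95), 1))
            cov = int(rng.integers(85, 101))
            add_row(pid, ref + "_a", ident, cov, 10.0 ** -float(rng.integers(30, 80)),
                    200.0 + float(np.round(rng.uniform(0, 50), 1)), ec)
            # a weaker but still eligible competitor: must lose on bitscore
            add_row(pid, ref + "_b", max(41.0, ident - 10), max(81, cov - 3),
                    1e-20, 150.0, ec)
            # an ineligible decoy failing the identity cutoff
            add_row(pid, ref + "_c", 35.0, cov, 1e-40, 300.0, ec)
            expected[pid] = ref + "_a"

    # dedicated boundary queries: one hit each, sitting exactly on a cutoff
    boundary = []
    for name, ident, cov, ev in [("b_ident40", 40.0, 95, 1e-30),
                                 ("b_qcov80", 75.0, 80, 1e-30),
                                 ("b_eval15", 75.0, 95, 1e-15)]:
        qid = name
        qlens[qid] = 100
        p2g[qid] = genome_ids[0]
        add_row(qid, "ref_boundary", ident, cov, ev, 250.0, "1.1.1.1")
        boundary.append(qid)

    hits = pd.DataFrame(rows)
    return EnzymeWorld(hits=hits, query_lengths=qlens, protein_to_genome=p2g,
                       genome_taxonomy=dict(GENOMES), expected_best=expected,
                       ec_to_genomes=ec_to_genomes, boundary_queries=boundary)
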