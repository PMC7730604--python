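"""Synthetic genome with planted LTR retrotransposons and full ground truth.

The generator emulates the evidence the survey consumes, so every pipeline
stage can be tested offline against known truth:

* elements whose 3' LTR is a mutated copy of the 5' LTR at controlled
  per-site transition/transversion rates (the simulation inverse of the
  K2P dating step);
* internal ORFs carrying recognisable peptide tags per canonical domain and
  a controlled number of CCHC zinc-knuckle (RBM) motifs in GAG;
* per-sample expression evidence (read counts + depth bedGraph) realising
  target RPKM and breadth-of-coverage values, including decoy elements that
  the expression cascade must reject;
* per-cultivar genomic depth over elements and single-copy reference genes
  realising planted copy-number multipliers with multiplicative noise;
* genes planted at controlled distances (inside / overlapping / close /
  distant) relative to their elements.

Background sequence is i.i.d. uniform nucleotides; alignment-level realism
(reads, sequencing errors, nested or solo LTRs) is out of scope — the
generator writes what the upstream aligners would have produced.  One
pseudo-random stream per logical component (plans, sequences, placement,
expression, cultivar noise) is derived from the master seed so that e.g.
adding samples does not perturb the genome.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from exrte.insertion_age import DEFAULT_RATE, k2p_distance

logger = logging.getLogger(__name__)

#: Peptide tags marking each canonical domain in planted ORFs.  They avoid
#: C and H so they can never create or disturb an RBM motif.
DOMAIN_TAGS = {
    "GAG": "GWKDLVNEAGQRTF",
    "AP": "APDKLVRGQENWTS",
    "INT": "INTGRLVDKEQWSA",
    "RT": "RTDKLGVEQWSAPM",
    "RH": "RNSEDKLGVQWAPT",
}

#: Filler alphabet for planted proteins: no C or H (RBM control), no M
#: (keeps planted start codons maximal).
_FILLER_AA = "ADEFGIKLNPQRSTVWY"

_CLADES = {
    "Ale": "Ty1/Copia",
    "Ivana": "Ty1/Copia",
    "Tork": "Ty1/Copia",
    "Reina": "Ty3/Gypsy",
    "CRM": "Ty3/Gypsy",
    "Retand": "Ty3/Gypsy",
    "Tekay": "Ty3/Gypsy",
}

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for aa in _CODONS_BY_AA:
    _CODONS_BY_AA[aa].sort()


def mutate_ltr(seq: str, p_rate: float, q_rate: float, seed) -> str:
    """Mutate a sequence site-wise at given transition/transversion rates.

    Each site independently receives a transition (A<->G, C<->T) with
    probability ``p_rate`` or a transversion (uniform over the two targets)
    with probability ``q_rate``; no indels.  ``seed`` may be an integer or a
    :class:`numpy.random.Generator`.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    if any(b not in "ACGT" for b in seq):
        raise ValueError("sequence must be over {A,C,G,T}")
    if p_rate < 0 or q_rate < 0 or p_rate + q_rate > 1:
        raise ValueError("need p_rate, q_rate >= 0 and p_rate + q_rate <= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(len(seq))
    pick = rng.integers(0, 2, len(seq))
    out = []
    for i, base in enumerate(seq):
        if u[i] < p_rate:
            out.append(_TRANSITION[base])
        elif u[i] < p_rate + q_rate:
            out.append(_TRANSVERSIONS[base][pick[i]])
        else:
            out.append(base)
    return "".join(out)


@dataclass
class OrfPlan:
    """One planted ORF: domain, protein length (aa), motif count, and the
    domain-match length (aa) to report in the annotation."""

    domain: str
    aa_len: int = 120
    rbm_count: int = 0
    match_aa: int = 100


@dataclass
class RtePlan:
    """Planted properties of one element before placement."""

    expressed: bool
    p_rate: float
    q_rate: float
    orfs: list[OrfPlan]
    rpkm: dict[str, float]
    breadth: dict[str, float]
    copy_multipliers: dict[str, float]
    gene_relation: str | None
    clade: str
    orfs_reverse: bool = False
    decoy_type: str | None = None


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic survey.

    Defaults give a ~1 Mb genome with 50 planted elements, 5 RNA-seq samples
    spanning stressed and non-stressed conditions, and 13 cultivars — a
    desk-scale analogue of the original survey design.
    """

    chrom_count: int = 2
    chrom_len: int = 500_000
    n_rte: int = 50
    ltr_len: int = 400
    n_ref_genes: int = 5
    ref_gene_len: int = 1500
    gene_len: int = 1200
    samples: dict[str, str] = field(
        default_factory=lambda: {
            "leaf": "non-stressed",
            "root": "non-stressed",
            "nacl_3h": "stressed",
            "peg_12h": "stressed",
            "aba_leaf": "stressed",
        }
    )
    library_size: float = 20_000_000
    cultivars: list[str] = field(
        default_factory=lambda: [f"cv{i:02d}" for i in range(1, 14)]
    )
    frac_expressed: float = 0.3
    expressed_rpkm_range: tuple[float, float] = (1.0, 20.0)
    expressed_breadth_range: tuple[float, float] = (0.80, 0.95)
    decoy_rpkm_max: float = 0.05
    decoy_breadth_max: float = 0.20
    recent_frac: float = 0.5
    recent_p_range: tuple[float, float] = (0.001, 0.008)
    late_p_range: tuple[float, float] = (0.02, 0.10)
    q_to_p: float = 0.5
    depth_noise_cv: float = 0.05
    cultivar_base_depth_range: tuple[float, float] = (8.0, 15.0)
    frac_mobile: float = 0.4
    multiplier_range: tuple[float, float] = (2.0, 5.0)
    assembly_tag: str = "SYN1"
    mutation_rate: float = DEFAULT_RATE
    max_placement_retries: int = 1000
    #: minimum clearance between planted feature blocks (keeps planted
    #: proximity classes unambiguous: > close-gene threshold)
    placement_buffer: int = 1100


@dataclass
class RteTruth:
    """Ground truth for one planted element after placement."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    p_rate: float
    q_rate: float
    t_expected_years: float
    recency: str
    expressed: bool
    rpkm: dict[str, float]
    breadth: dict[str, float]
    read_counts: dict[str, int]
    orfs: list[dict]
    copy_multipliers: dict[str, float]
    gene_relation: str | None
    gene_id: str | None
    clade: str
    superfamily: str
    decoy_type: str | None


@dataclass
class SyntheticTruth:
    """Ground truth for a generated dataset."""

    seed: int
    rtes: dict[str, RteTruth]
    genes: dict[str, tuple[str, int, int]]
    ref_gene_ids: list[str]
    samples: dict[str, str]
    cultivars: list[str]
    files: dict[str, str]  # file names relative to the dataset directory

    def expressed_ids(self) -> set[str]:
        return {rid for rid, t in self.rtes.items() if t.expressed}

    def to_json(self, path: str | Path) -> None:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True, default=default)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _protein(plan: OrfPlan, rng: np.random.Generator) -> str:
    """Planted protein: start M, domain tag, ``rbm_count`` motifs, filler."""

    def filler(n: int) -> str:
        return "".join(
            np.array(list(_FILLER_AA))[rng.integers(0, len(_FILLER_AA), n)]
        )

    parts = ["M", filler(4), DOMAIN_TAGS[plan.domain], filler(3)]
    for _ in range(plan.rbm_count):
        motif = "C" + filler(2) + "C" + filler(4) + "H" + filler(4) + "C"
        parts.append(motif)
        parts.append(filler(2))
    body = "".join(parts)
    if len(body) > plan.aa_len:
        raise ValueError(f"aa_len {plan.aa_len} too short for planted content")
    return body + filler(plan.aa_len - len(body))


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for i, aa in enumerate(protein):
        if i == 0 and aa == "M":
            codons.append("ATG")
        else:
            options = _CODONS_BY_AA[aa]
            codons.append(options[rng.integers(0, len(options))])
    return "".join(codons)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _draw_plans(config: SimulationConfig, rng: np.random.Generator) -> list[RtePlan]:
    n = config.n_rte
    n_ex = round(config.frac_expressed * n)
    expressed_idx = set(rng.permutation(n)[:n_ex].tolist())
    stressed = [s for s, lab in config.samples.items() if lab == "stressed"]
    unstressed = [s for s, lab in config.samples.items() if lab == "non-stressed"]
    relations = ["distant", "close", "overlapped", "insertion", "distant"]
    clade_names = list(_CLADES)
    copia = [c for c in clade_names if _CLADES[c] == "Ty1/Copia"]

    plans: list[RtePlan] = []
    n_decoy_seen = 0
    n_ex_seen = 0
    for i in range(n):
        expressed = i in expressed_idx
        # -- age
        if rng.random() < config.recent_frac:
            p = rng.uniform(*config.recent_p_range)
        else:
            p = rng.uniform(*config.late_p_range)
        q = p * config.q_to_p

        # -- clade: expressed side biased to Ty1/Copia, emulating the
        #    enrichment the survey is designed to detect
        if expressed:
            clade = copia[rng.integers(0, len(copia))] if rng.random() < 0.7 else (
                clade_names[rng.integers(0, len(clade_names) - 1)]  # never Tekay
            )
        else:
            clade = clade_names[rng.integers(0, len(clade_names))]

        # -- domains
        p_gag = 0.8 if expressed else 0.35
        if rng.random() < (0.3 if expressed else 0.05):
            domains = ["GAG", "AP", "INT", "RT", "RH"]
        else:
            domains = ["RT"]
            if rng.random() < p_gag:
                domains.append("GAG")
            for d in ("AP", "INT", "RH"):
                if rng.random() < 0.5:
                    domains.append(d)
        decoy_type = None
        match_aa = 100
        if not expressed:
            decoy_type = ["ltr_only", "trace", "silent", "short_domain"][n_decoy_seen % 4]
            n_decoy_seen += 1
            if decoy_type == "short_domain":
                match_aa = int(rng.integers(10, 40))
        orfs = [
            OrfPlan(
                domain=d,
                aa_len=int(rng.integers(110, 140)),
                rbm_count=(int(rng.integers(1, 3)) if d == "GAG" and rng.random() < 0.7 else 0),
                match_aa=match_aa,
            )
            for d in domains
        ]

        # -- expression targets
        rpkm = {s: 0.0 for s in config.samples}
        breadth = {s: 0.0 for s in config.samples}
        if expressed:
            pattern = n_ex_seen % 3  # 0: non-stressed only, 1: stressed only, 2: both
            n_ex_seen += 1
            active = {0: unstressed, 1: stressed, 2: list(config.samples)}[pattern]
            for s in active:
                rpkm[s] = float(rng.uniform(*config.expressed_rpkm_range))
                breadth[s] = float(rng.uniform(*config.expressed_breadth_range))
        elif decoy_type == "ltr_only":
            s = list(config.samples)[int(rng.integers(0, len(config.samples)))]
            rpkm[s] = float(rng.uniform(0.5, 3.0))
            breadth[s] = float(rng.uniform(0.05, config.decoy_breadth_max))
        elif decoy_type == "trace":
            s = list(config.samples)[int(rng.integers(0, len(config.samples)))]
            rpkm[s] = float(rng.uniform(0.005, config.decoy_rpkm_max))
            breadth[s] = float(rng.uniform(0.6, 0.9))
        elif decoy_type == "short_domain":
            for s in config.samples:
                rpkm[s] = float(rng.uniform(*config.expressed_rpkm_range))
                breadth[s] = float(rng.uniform(*config.expressed_breadth_range))
        # "silent": all zero

        # -- copy-number multipliers (min across cultivars is exactly 1)
        multipliers = {c: 1.0 for c in config.cultivars}
        u = rng.random()
        if u < config.frac_mobile:
            k = int(rng.integers(2, 5))
        elif u < config.frac_mobile + 0.2:
            k = 1
        else:
            k = 0
        chosen = rng.permutation(len(config.cultivars))[:k]
        for ci in chosen:
            multipliers[config.cultivars[ci]] = float(
                rng.uniform(*config.multiplier_range)
            )

        plans.append(
            RtePlan(
                expressed=expressed,
                p_rate=float(p),
                q_rate=float(q),
                orfs=orfs,
                rpkm=rpkm,
                breadth=breadth,
                copy_multipliers=multipliers,
                gene_relation=relations[i % len(relations)],
                clade=clade,
                orfs_reverse=(i % 7 == 3),
                decoy_type=decoy_type,
            )
        )
    return plans


def _build_element(
    plan: RtePlan, config: SimulationConfig, rng: np.random.Generator
) -> tuple[str, tuple[int, int], tuple[int, int], list[dict]]:
    """Element sequence, local LTR intervals, and local ORF records."""
    ltr5_seq = _rand_seq(rng, config.ltr_len)
    blocks: list[str] = [_rand_seq(rng, 120)]
    length = 120
    orf_local: list[dict] = []
    for orf in plan.orfs:
        protein = _protein(orf, rng)
        nt = _reverse_translate(protein, rng)
        blocks.append("TAG")  # barrier: makes the planted ATG the maximal start
        length += 3
        start = length
        blocks.append(nt)
        length += len(nt)
        orf_local.append(
            {
                "domain": orf.domain,
                "start": start,
                "end": start + len(nt),
                "aa_len": orf.aa_len,
                "rbm_count": orf.rbm_count,
                "match_aa": orf.match_aa,
                "strand": "+",
            }
        )
        blocks.append("TAA")
        length += 3
        spacer = _rand_seq(rng, 60)
        blocks.append(spacer)
        length += 60
    internal = "".join(blocks)
    if plan.orfs_reverse:
        n = len(internal)
        internal = _revcomp(internal)
        for rec in orf_local:
            rec["start"], rec["end"] = n - rec["end"], n - rec["start"]
            rec["strand"] = "-"
    ltr3_seq = mutate_ltr(ltr5_seq, plan.p_rate, plan.q_rate, rng)
    seq = ltr5_seq + internal + ltr3_seq
    offset = config.ltr_len
    for rec in orf_local:
        rec["start"] += offset
        rec["end"] += offset
    ltr5 = (0, config.ltr_len)
    ltr3 = (len(seq) - config.ltr_len, len(seq))
    return seq, ltr5, ltr3, orf_local


def _place(
    occupied: dict[int, list[tuple[int, int]]],
    config: SimulationConfig,
    rng: np.random.Generator,
    block_len: int,
    upstream: int = 0,
    downstream: int = 0,
) -> tuple[int, int]:
    """Find a free (chrom index, start) for a block; reserve it with buffer."""
    buffer = config.placement_buffer
    total = upstream + block_len + downstream
    for _ in range(config.max_placement_retries):
        ci = int(rng.integers(0, config.chrom_count))
        if config.chrom_len <= total + 2 * buffer:
            break
        start = int(rng.integers(buffer + upstream, config.chrom_len - block_len - downstream - buffer))
        lo, hi = start - upstream - buffer, start + block_len + downstream + buffer
        if all(hi <= s or e <= lo for s, e in occupied[ci]):
            occupied[ci].append((lo, hi))
            return ci, start
    raise RuntimeError(
        "could not place a planted feature without overlap; "
        "increase chrom_len or reduce n_rte"
    )


def _gene_layout(
    relation: str | None, start: int, end: int, gene_len: int, rng: np.random.Generator
) -> tuple[int, int] | None:
    """Gene interval realising a planted proximity class for element [start, end)."""
    if relation is None:
        return None
    if relation == "insertion":
        return start - 200, end + max(200, gene_len - (end - start) - 200)
    if relation == "overlapped":
        return end - 150, end - 150 + gene_len
    if relation == "close":
        gap = int(rng.integers(50, 900))
        return end + gap, end + gap + gene_len
    if relation == "distant":
        gap = int(rng.integers(1500, 6000))
        return end + gap, end + gap + gene_len
    raise ValueError(f"unknown gene relation {relation!r}")


def generate_dataset(
    config: SimulationConfig, seed: int, outdir: str | Path
) -> SyntheticTruth:
    """Generate the full synthetic dataset; returns the ground truth.

    Writes genome FASTA, element and gene GFF3, per-sample depth bedGraph and
    read-count/library-size TSVs, the per-cultivar depth TSV, and a JSON
    truth dump into ``outdir``.  Identical (config, seed) gives byte-identical
    files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    plan_rng, seq_rng, place_rng, expr_rng, cult_rng = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    plans = _draw_plans(config, plan_rng)

    # chromosome background first so sequence content is independent of plans
    chrom_names = [f"chr{i + 1:02d}" for i in range(config.chrom_count)]
    chroms = [
        np.array(list(_rand_seq(seq_rng, config.chrom_len))) for _ in chrom_names
    ]
    elements = [_build_element(plan, config, seq_rng) for plan in plans]

    # placement: elements (with their planted genes), then reference genes
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(config.chrom_count)}
    truths: dict[str, RteTruth] = {}
    genes: dict[str, tuple[str, int, int]] = {}
    placed: list[tuple[str, RteTruth, str]] = []  # (id, truth, seq)
    for idx, (plan, (seq, ltr5, ltr3, orf_local)) in enumerate(zip(plans, elements)):
        upstream = 250 if plan.gene_relation == "insertion" else 0
        downstream = {
            "insertion": max(250, config.gene_len - len(seq)),
            "overlapped": config.gene_len,
            "close": 900 + config.gene_len,
            "distant": 6000 + config.gene_len,
            None: 0,
        }[plan.gene_relation]
        ci, start = _place(occupied, config, place_rng, len(seq), upstream, downstream)
        end = start + len(seq)
        chrom = chrom_names[ci]
        rte_id = f"TE{ci + 1:02d}s{start + 1}{config.assembly_tag}"
        gene_iv = _gene_layout(plan.gene_relation, start, end, config.gene_len, place_rng)
        gene_id = None
        if gene_iv is not None:
            gene_id = f"gene_{rte_id}"
            genes[gene_id] = (chrom, gene_iv[0], gene_iv[1])
        k_true = k2p_distance(plan.p_rate, plan.q_rate)
        t_true = k_true / (2 * config.mutation_rate)
        read_counts = {
            s: int(round(plan.rpkm[s] * len(seq) * config.library_size / 1e9))
            for s in config.samples
        }
        truth = RteTruth(
            id=rte_id,
            chrom=chrom,
            start=start,
            end=end,
            strand="+",
            ltr5=(start + ltr5[0], start + ltr5[1]),
            ltr3=(start + ltr3[0], start + ltr3[1]),
            p_rate=plan.p_rate,
            q_rate=plan.q_rate,
            t_expected_years=t_true,
            recency="recent" if t_true < 5e5 else "late",
            expressed=plan.expressed,
            rpkm=plan.rpkm,
            breadth=plan.breadth,
            read_counts=read_counts,
            orfs=[
                {**rec, "start": rec["start"], "end": rec["end"]} for rec in orf_local
            ],
            copy_multipliers=plan.copy_multipliers,
            gene_relation=plan.gene_relation,
            gene_id=gene_id,
            clade=plan.clade,
            superfamily=_CLADES[plan.clade],
            decoy_type=plan.decoy_type,
        )
        truths[rte_id] = truth
        placed.append((rte_id, truth, seq))
        chroms[ci][start:end] = list(seq)

    ref_gene_ids = []
    for j in range(config.n_ref_genes):
        ci, start = _place(occupied, config, place_rng, config.ref_gene_len)
        gid = f"refgene_{j + 1}"
        ref_gene_ids.append(gid)
        genes[gid] = (chrom_names[ci], start, start + config.ref_gene_len)

    files = _write_outputs(
        outdir, config, chrom_names, chroms, truths, genes, ref_gene_ids, expr_rng, cult_rng
    )
    truth = SyntheticTruth(
        seed=seed,
        rtes=truths,
        genes=genes,
        ref_gene_ids=ref_gene_ids,
        samples=dict(config.samples),
        cultivars=list(config.cultivars),
        files=files,
    )
    truth.to_json(outdir / "truth.json")
    return truth


def _write_outputs(
    outdir: Path,
    config: SimulationConfig,
    chrom_names: list[str],
    chroms: list[np.ndarray],
    truths: dict[str, RteTruth],
    genes: dict[str, tuple[str, int, int]],
    ref_gene_ids: list[str],
    expr_rng: np.random.Generator,
    cult_rng: np.random.Generator,
) -> dict[str, str]:
    files: dict[str, str] = {}

    # -- genome FASTA
    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for name, arr in zip(chrom_names, chroms):
            fh.write(f">{name}\n")
            seq = "".join(arr)
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    files["genome"] = fasta.name

    # -- element GFF3 (1-based inclusive)
    gff = outdir / "rtes.gff3"
    ordered = sorted(truths.values(), key=lambda t: (t.chrom, t.start))
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in ordered:
            attrs = f"ID={t.id};superfamily={t.superfamily};clade={t.clade}"
            fh.write(
                f"{t.chrom}\texrte_sim\tLTR_retrotransposon\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for n, (s, e) in enumerate((t.ltr5, t.ltr3), 1):
                fh.write(
                    f"{t.chrom}\texrte_sim\tlong_terminal_repeat\t{s + 1}\t{e}\t.\t{t.strand}\t.\tID={t.id}_ltr{n};Parent={t.id}\n"
                )
            for n, orf in enumerate(t.orfs):
                s = t.start + orf["start"]
                e = t.start + orf["end"]
                fh.write(
                    f"{t.chrom}\texrte_sim\tprotein_match\t{s + 1}\t{e}\t.\t{orf['strand']}\t.\t"
                    f"ID={t.id}_pm{n};Parent={t.id};Name={orf['domain']};aa_length={orf['match_aa']}\n"
                )
    files["rte_gff"] = gff.name

    # -- gene GFF3
    gene_gff = outdir / "genes.gff3"
    with open(gene_gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, (chrom, s, e) in sorted(genes.items(), key=lambda kv: (kv[1][0], kv[1][1])):
            kind = "reference_single_copy" if gid in ref_gene_ids else "planted"
            fh.write(
                f"{chrom}\texrte_sim\tgene\t{s + 1}\t{e}\t.\t+\t.\tID={gid};gene_kind={kind}\n"
            )
    files["gene_gff"] = gene_gff.name

    # -- expression: counts, library sizes, per-sample bedGraph
    counts_path = outdir / "counts.tsv"
    with open(counts_path, "w") as fh:
        fh.write("rte_id\tsample\tread_count\n")
        for t in ordered:
            for s in config.samples:
                fh.write(f"{t.id}\t{s}\t{t.read_counts[s]}\n")
    files["counts"] = counts_path.name

    lib_path = outdir / "library_sizes.tsv"
    with open(lib_path, "w") as fh:
        fh.write("sample\tlibrary_size\tcondition\n")
        for s, label in config.samples.items():
            fh.write(f"{s}\t{int(config.library_size)}\t{label}\n")
    files["library_sizes"] = lib_path.name

    for sample in config.samples:
        lines = []
        for t in ordered:
            length = t.end - t.start
            cov_len = int(round(t.breadth[sample] * length))
            if cov_len <= 0:
                continue
            offset = int(expr_rng.integers(0, length - cov_len + 1))
            depth = max(1, int(round(t.read_counts[sample] * 100 / cov_len)))
            lines.append((t.chrom, t.start + offset, t.start + offset + cov_len, depth))
        path = outdir / f"depth_{sample}.bedgraph"
        with open(path, "w") as fh:
            for chrom, s, e, d in sorted(lines):
                fh.write(f"{chrom}\t{s}\t{e}\t{d}\n")
        files[f"depth_{sample}"] = path.name

    # -- per-cultivar genomic depth over elements and reference genes
    base_depth = {
        c: float(cult_rng.uniform(*config.cultivar_base_depth_range))
        for c in config.cultivars
    }
    sigma = config.depth_noise_cv
    depth_path = outdir / "cultivar_depth.tsv"
    with open(depth_path, "w") as fh:
        fh.write("feature_id\tfeature_type\t" + "\t".join(config.cultivars) + "\n")
        for t in ordered:
            vals = []
            for c in config.cultivars:
                noise = float(np.exp(cult_rng.normal(-0.5 * sigma**2, sigma))) if sigma > 0 else 1.0
                vals.append(base_depth[c] * t.copy_multipliers[c] * noise)
            fh.write(t.id + "\trte\t" + "\t".join(f"{v:.6f}" for v in vals) + "\n")
        for gid in ref_gene_ids:
            vals = []
            for c in config.cultivars:
                noise = float(np.exp(cult_rng.normal(-0.5 * sigma**2, sigma))) if sigma > 0 else 1.0
                vals.append(base_depth[c] * noise)
            fh.write(gid + "\tref_gene\t" + "\t".join(f"{v:.6f}" for v in vals) + "\n")
    files["cultivar_depth"] = depth_path.name
    return files
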