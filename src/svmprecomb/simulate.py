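"""Synthetic multi-domain gene-family simulator with ground truth.

Emulates the evolution of an SVMP-like gene family: a P-III ancestral
transcript (catalytic + disintegrin + cysteine-rich coding domains, a stop
codon and a short, slowly evolving 3'UTR) duplicates along a random
bifurcating genealogy; coding regions accumulate substitutions roughly an
order of magnitude faster than the 3'UTR; duplications may lose the
cysteine-rich domain (P-III -> P-II) and subsequently the disintegrin domain
(P-II -> P-I); interclass recombination copies a donor's 5' segment into an
acceptor (transcript mode: verbatim; genomic mode: followed by further
substitutions); short repeated / reverse-complementary motifs can be planted.
Every event is logged, making detector benchmarking exact.

Substitutions follow a Jukes-Cantor site process: event counts are Poisson
with mean rate x sites per branch, each event replacing the base at a uniform
site with a uniform different base, so ``jc_correct`` is the matching distance
estimator. Purifying selection is modelled at the protein level: substitutions
that would create an in-frame stop codon, or change a constrained functional
residue (the zinc-motif anchor positions H/E/H/G/H and the RGD / ECD
tripeptides), are redrawn among admissible alternatives — synonymous changes
and changes at unconstrained motif positions pass through. The stop codon
itself is never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa import MultipleAlignment
from .recomb import ShiftSegmentation
from .seqio import SequenceRecord, reverse_complement, translate

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

# Codons used to write protected motifs into the ancestor (arbitrary but fixed).
_AA_CODON = {
    "H": "CAT", "E": "GAA", "L": "CTG", "G": "GGA", "N": "AAT", "M": "ATG",
    "R": "CGT", "D": "GAT", "C": "TGT",
}


class SimulationError(ValueError):
    """Raised when a configuration cannot produce a valid family."""


@dataclass(frozen=True)
class DomainLengths:
    catalytic: int = 642
    disintegrin: int = 279
    cysrich: int = 330
    utr: int = 80

    def __post_init__(self) -> None:
        for name in ("catalytic", "disintegrin", "cysrich"):
            if getattr(self, name) % 3:
                raise SimulationError(f"{name} length must be a multiple of 3")
        if min(self.catalytic, self.disintegrin, self.cysrich) < 60:
            raise SimulationError("coding domains must be >= 60 nt")


@dataclass(frozen=True)
class PlantedMotif:
    k: int
    source_start: int  # 1-based, template coordinates
    target_start: int
    orientation: str = "direct"  # direct | reverse-complement


@dataclass
class SimulationConfig:
    seed: int
    n_leaves: int = 10
    domain_lengths: DomainLengths = field(default_factory=DomainLengths)
    sub_rate_coding: float = 0.02  # expected substitutions/site per branch
    sub_rate_utr: float | None = None  # default: sub_rate_coding / 10
    p_loss_cysrich: float = 0.3
    p_loss_disintegrin: float = 0.15
    n_recombinations: int = 0
    recomb_mode: str = "transcript"  # transcript | genomic
    breakpoint_range: tuple[int, int] = (365, 600)
    #: admissible donor/acceptor sequence divergence (p-distance over shared
    #: sites); interclass recombination between near-identical or saturated
    #: lineages is neither detectable nor the modelled scenario
    donor_p_range: tuple[float, float] = (0.08, 0.15)
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    protect_motifs: bool = True

    def __post_init__(self) -> None:
        if self.n_leaves < 3:
            raise SimulationError("n_leaves must be >= 3")
        if self.sub_rate_coding < 0:
            raise SimulationError("rates must be >= 0")
        if self.sub_rate_utr is None:
            self.sub_rate_utr = self.sub_rate_coding / 10.0
        for p in (self.p_loss_cysrich, self.p_loss_disintegrin):
            if not (0 <= p <= 1):
                raise SimulationError("loss probabilities must be in [0, 1]")
        if self.recomb_mode not in ("transcript", "genomic"):
            raise SimulationError(f"unknown recomb_mode {self.recomb_mode!r}")
        lo, hi = self.breakpoint_range
        if not (1 <= lo <= hi <= self.domain_lengths.catalytic):
            raise SimulationError(
                "breakpoint_range must lie within the shared catalytic region"
            )


@dataclass
class Event:
    kind: str  # duplication | loss | recombination
    detail: dict


@dataclass
class SimulatedFamily:
    records: list[SequenceRecord]
    true_classes: dict[str, str]
    event_log: list[Event]
    true_alignment: MultipleAlignment
    config: SimulationConfig
    #: genealogy: child node id -> parent node id ("root" has parent None)
    parents: dict[str, str | None] = field(default_factory=dict)
    #: leaf name -> node id
    leaf_nodes: dict[str, str] = field(default_factory=dict)
    #: child node id -> number of realized substitution events (coding, utr)
    branch_substitutions: dict[str, tuple[int, int]] = field(default_factory=dict)
    #: nt sites under selection: the stop codon (never mutated) plus codons
    #: whose amino acid is constrained (only synonymous changes allowed)
    protected_sites: frozenset = frozenset()

    def n_branches_between(self, leaf_a: str, leaf_b: str) -> int:
        """Number of branches on the genealogy path between two leaves."""

        def ancestry(leaf: str) -> list[str]:
            node = self.leaf_nodes[leaf]
            path = [node]
            while self.parents[node] is not None:
                node = self.parents[node]
                path.append(node)
            return path

        pa, pb = ancestry(leaf_a), ancestry(leaf_b)
        seen = {n: i for i, n in enumerate(pa)}
        for j, node in enumerate(pb):
            if node in seen:
                return seen[node] + j
        raise ValueError("disconnected genealogy")


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------


def _motif_codons(protein: str, aa_start: int) -> tuple[str, list[int]]:
    """Nt string of a protein motif plus the 0-based nt offsets it occupies."""
    nt = "".join(_AA_CODON[a] for a in protein)
    start_nt = (aa_start - 1) * 3
    return nt, list(range(start_nt, start_nt + len(nt)))


def _build_template(cfg: SimulationConfig, rng: np.random.Generator):
    """Random ancestral P-III transcript with constrained functional motifs.

    Returns the template array, domain spans, the fully-protected nucleotide
    sites (the stop codon), and a codon-start -> required-amino-acid map
    expressing protein-level purifying selection on motif residues.
    """
    dl = cfg.domain_lengths
    coding_len = dl.catalytic + dl.disintegrin + dl.cysrich
    n_codons = coding_len // 3
    codons = []
    non_stop = [a + b + c for a in _BASES for b in _BASES for c in _BASES
                if a + b + c not in _STOPS]
    idx = rng.integers(0, len(non_stop), size=n_codons)
    codons = [non_stop[i] for i in idx]
    seq = list("".join(codons))

    aa_constraints: dict[int, str] = {}  # codon-start nt offset -> required aa

    def plant(protein: str, aa_start: int, anchors: set[int] | None = None) -> None:
        nt, offsets = _motif_codons(protein, aa_start)
        for off, base in zip(offsets, nt):
            seq[off] = base
        for i, aa in enumerate(protein):
            if anchors is None or i in anchors:
                aa_constraints[(aa_start - 1 + i) * 3] = aa

    cat_aa = dl.catalytic // 3
    dis_aa_start = cat_aa + 1
    # zinc-binding motif HELGHNLGMEH (consensus HEXXHXXGXXH) mid-catalytic;
    # only the anchor residues are under selection, the X positions drift
    zinc_start = max(2, int(cat_aa * 0.66))
    plant("HELGHNLGMEH", zinc_start, anchors={0, 1, 4, 7, 10})
    # RGD and ECD tripeptides in the disintegrin / disintegrin-like region
    dis_aa = dl.disintegrin // 3
    plant("RGD", dis_aa_start + int(dis_aa * 0.6))
    plant("ECD", dis_aa_start + int(dis_aa * 0.75))

    coding = "".join(seq)
    utr = "".join(_BASES[i] for i in rng.integers(0, 4, size=dl.utr))
    template = coding + "TAA" + utr
    stop_sites = frozenset({coding_len, coding_len + 1, coding_len + 2})
    if not cfg.protect_motifs:
        aa_constraints = {}
    spans = {
        "catalytic": (0, dl.catalytic),
        "disintegrin": (dl.catalytic, dl.catalytic + dl.disintegrin),
        "cysrich": (dl.catalytic + dl.disintegrin, coding_len),
        "stop": (coding_len, coding_len + 3),
        "utr": (coding_len + 3, len(template)),
    }
    return (
        np.frombuffer(template.encode(), dtype=np.uint8).copy(),
        spans,
        stop_sites,
        aa_constraints,
    )


_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


_CODON_AA: dict[bytes, str] = {}


def _codon_aa(codon: bytes) -> str:
    aa = _CODON_AA.get(codon)
    if aa is None:
        aa = translate(codon.decode(), frame=0)
        _CODON_AA[codon] = aa
    return aa


def _mutate(
    seq: np.ndarray,
    sites: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    coding_end: int,
    aa_constraints: dict[int, str] | None = None,
) -> int:
    """Apply a Poisson(rate x len(sites)) JC substitution process in place.

    Events landing in the coding region are redrawn among the alternative
    bases that neither create an in-frame stop codon nor violate an
    amino-acid constraint on the codon (purifying selection); an event with
    no admissible alternative is dropped. Returns the number of applied
    events.
    """
    if rate <= 0 or len(sites) == 0:
        return 0
    n_events = rng.poisson(rate * len(sites))
    applied = 0
    for _ in range(n_events):
        site = int(sites[rng.integers(0, len(sites))])
        old = seq[site]
        choices = [b for b in _BASE_CODES if b != old]
        if site < coding_end:
            codon_start = site - site % 3
            codon = bytearray(seq[codon_start : codon_start + 3])
            required = aa_constraints.get(codon_start) if aa_constraints else None
            ok = []
            for alt in choices:
                codon[site % 3] = alt
                cod = bytes(codon)
                if cod in (b"TAA", b"TAG", b"TGA"):
                    continue
                if required is not None and _codon_aa(cod) != required:
                    continue
                ok.append(alt)
            if not ok:
                continue
            new = ok[rng.integers(0, len(ok))]
        else:
            new = choices[rng.integers(0, len(choices))]
        seq[site] = new
        applied += 1
    return applied


# ---------------------------------------------------------------------------
# Family simulation
# ---------------------------------------------------------------------------


def simulate_family(cfg: SimulationConfig) -> SimulatedFamily:
    """Simulate a gene family; deterministic under a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    template, spans, stop_sites, aa_constraints = _build_template(cfg, rng)
    protected = frozenset(stop_sites) | frozenset(
        off + i for off in aa_constraints for i in range(3)
    )
    tlen = len(template)
    coding_end = spans["cysrich"][1]

    events: list[Event] = []
    parents: dict[str, str | None] = {"n0": None}
    branch_subs: dict[str, tuple[int, int]] = {}

    # lineage state: node id, sequence array, presence mask, lost-domain set
    class Lineage:
        __slots__ = ("node", "seq", "present", "lost")

        def __init__(self, node, seq, present, lost):
            self.node = node
            self.seq = seq
            self.present = present
            self.lost = lost

    root = Lineage("n0", template.copy(), np.ones(tlen, dtype=bool), set())
    lineages = [root]
    counter = 1

    def evolve_branch(lin: Lineage) -> None:
        nonlocal branch_subs
        hard = np.zeros(tlen, dtype=bool)
        hard[list(stop_sites)] = True
        coding_mask = np.zeros(tlen, dtype=bool)
        coding_mask[: coding_end] = True
        utr_mask = np.zeros(tlen, dtype=bool)
        utr_mask[spans["utr"][0] : spans["utr"][1]] = True
        coding_sites = np.nonzero(lin.present & coding_mask & ~hard)[0]
        utr_sites = np.nonzero(lin.present & utr_mask & ~hard)[0]
        nc = _mutate(lin.seq, coding_sites, cfg.sub_rate_coding, rng, coding_end, aa_constraints)
        nu = _mutate(lin.seq, utr_sites, cfg.sub_rate_utr, rng, coding_end)
        branch_subs[lin.node] = (nc, nu)

    # Yule process: grow to n_leaves, evolving each branch as it is created.
    evolve_branch(root)
    while len(lineages) < cfg.n_leaves:
        parent = lineages[rng.integers(0, len(lineages))]
        child_a = Lineage(f"n{counter}", parent.seq.copy(), parent.present.copy(), set(parent.lost))
        child_b = Lineage(f"n{counter + 1}", parent.seq.copy(), parent.present.copy(), set(parent.lost))
        counter += 2
        parents[child_a.node] = parent.node
        parents[child_b.node] = parent.node
        events.append(Event("duplication", {"parent": parent.node, "children": (child_a.node, child_b.node)}))
        # domain loss on the newly created copy (P-III -> P-II -> P-I order)
        if "cysrich" not in child_b.lost:
            if rng.random() < cfg.p_loss_cysrich:
                child_b.lost.add("cysrich")
                s, e = spans["cysrich"]
                child_b.present[s:e] = False
                events.append(Event("loss", {"id": child_b.node, "domain": "cysrich"}))
        elif "disintegrin" not in child_b.lost:
            if rng.random() < cfg.p_loss_disintegrin:
                child_b.lost.add("disintegrin")
                s, e = spans["disintegrin"]
                child_b.present[s:e] = False
                events.append(Event("loss", {"id": child_b.node, "domain": "disintegrin"}))
        evolve_branch(child_a)
        evolve_branch(child_b)
        lineages.remove(parent)
        lineages.extend([child_a, child_b])

    leaves = {f"seq{i + 1}": lin for i, lin in enumerate(lineages)}
    leaf_nodes = {name: lin.node for name, lin in leaves.items()}

    def leaf_class(lin: Lineage) -> str:
        if "disintegrin" in lin.lost:
            return "P-I"
        if "cysrich" in lin.lost:
            return "P-II"
        return "P-III"

    true_classes = {name: leaf_class(lin) for name, lin in leaves.items()}

    # recombination events
    names = sorted(leaves)

    def pair_p_distance(na: str, nb: str) -> float:
        la, lb = leaves[na], leaves[nb]
        shared = la.present & lb.present
        n = int(shared.sum())
        if n == 0:
            return 1.0
        return float((la.seq[shared] != lb.seq[shared]).sum()) / n

    for _ in range(cfg.n_recombinations):
        acceptors = [n for n in names if true_classes[n] in ("P-II", "P-III")]
        plo, phi = cfg.donor_p_range
        ok_pairs = [
            (acc, don)
            for acc in acceptors
            for don in names
            if don != acc
            and true_classes[don] != true_classes[acc]
            and plo <= pair_p_distance(acc, don) <= phi
        ]
        if not ok_pairs:
            raise SimulationError(
                "no interclass donor/acceptor pair in the configured divergence range"
            )
        acc_name, don_name = ok_pairs[rng.integers(0, len(ok_pairs))]
        acc, don = leaves[acc_name], leaves[don_name]
        lo, hi = cfg.breakpoint_range
        bp = None
        for _attempt in range(50):
            cand = int(rng.integers(lo, hi + 1))
            junction_start = cand - cand % 3
            trial = acc.seq.copy()
            trial[:cand] = don.seq[:cand]
            codon = bytes(trial[junction_start : junction_start + 3])
            if codon not in (b"TAA", b"TAG", b"TGA"):
                bp = cand
                break
        if bp is None:
            raise SimulationError("could not place a stop-free breakpoint")
        # The breakpoint is identifiable only up to the run of pre-event
        # acceptor/donor identity around it: copying don[1..b] yields the
        # same observable acceptor for every b in [b_min, b_max], so the
        # ground truth is that interval, with bp an arbitrary representative.
        obs = acc.present  # observable acceptor sites
        b_max = bp
        while b_max < tlen and (not obs[b_max] or acc.seq[b_max] == don.seq[b_max]):
            b_max += 1
        b_min = bp
        while b_min > 1 and (not obs[b_min - 1] or acc.seq[b_min - 1] == don.seq[b_min - 1]):
            b_min -= 1
        acc.seq[:bp] = don.seq[:bp]
        if cfg.recomb_mode == "genomic":
            hard = np.zeros(tlen, dtype=bool)
            hard[list(stop_sites)] = True
            sites = np.nonzero(acc.present & ~hard)[0]
            sites = sites[sites < coding_end]
            _mutate(acc.seq, sites, cfg.sub_rate_coding, rng, coding_end, aa_constraints)
        events.append(
            Event(
                "recombination",
                {
                    "acceptor": acc_name,
                    "donor": don_name,
                    "breakpoint_nt": bp,
                    "breakpoint_interval": (b_min, b_max),
                    "mode": cfg.recomb_mode,
                },
            )
        )

    # planted repeat/complement motifs (template coordinates, post-evolution)
    for motif in cfg.planted_motifs:
        s0 = motif.source_start - 1
        t0 = motif.target_start - 1
        for lin in leaves.values():
            if not (lin.present[s0 : s0 + motif.k].all() and lin.present[t0 : t0 + motif.k].all()):
                continue
            segment = lin.seq[s0 : s0 + motif.k].tobytes().decode()
            if motif.orientation == "reverse-complement":
                segment = reverse_complement(segment)
            lin.seq[t0 : t0 + motif.k] = np.frombuffer(segment.encode(), dtype=np.uint8)

    records = []
    aln_rows = []
    for name in names:
        lin = leaves[name]
        chars = lin.seq.tobytes().decode()
        degapped = "".join(c for c, p in zip(chars, lin.present) if p)
        records.append(SequenceRecord(name, degapped, "nt"))
        aln_rows.append("".join(c if p else "-" for c, p in zip(chars, lin.present)))
    true_aln = MultipleAlignment(names, aln_rows, "nt")

    return SimulatedFamily(
        records=records,
        true_classes=true_classes,
        event_log=events,
        true_alignment=true_aln,
        config=cfg,
        parents=parents,
        leaf_nodes=leaf_nodes,
        branch_substitutions=branch_subs,
        protected_sites=protected,
    )


# ---------------------------------------------------------------------------
# Breakpoint recovery evaluation
# ---------------------------------------------------------------------------


@dataclass
class DetectedBreakpoint:
    """One detected breakpoint: the triplet scanned and per-id positions."""

    triplet: tuple[str, str, str]
    positions: dict[str, int]  # id -> 1-based position in ungapped coordinates


@dataclass
class RecoveryResult:
    precision: float
    recall: float
    offsets: list[int]
    n_true: int
    n_detected: int
    zero_predictions: bool = False


def evaluate_breakpoint_recovery(
    event_log: list[Event],
    detected: list[DetectedBreakpoint],
    tolerance_nt: int = 15,
) -> RecoveryResult:
    """Match detected breakpoints against logged recombination events.

    A true event is recovered when some detection on a triplet containing
    both acceptor and donor lies within ``tolerance_nt`` of the true
    breakpoint (compared in the acceptor's own coordinates). Because the
    breakpoint of a copy event is identifiable only up to the run of
    pre-event acceptor/donor identity around it, the offset is measured to
    the logged ``breakpoint_interval`` of equivalent positions (zero inside
    it); events logged without an interval fall back to the scalar. With
    zero predictions, precision is reported as 1.0 with a flag.
    """
    truths = [e.detail for e in event_log if e.kind == "recombination"]

    def _offset(truth: dict, pos: int) -> int:
        b_min, b_max = truth.get(
            "breakpoint_interval", (truth["breakpoint_nt"], truth["breakpoint_nt"])
        )
        if b_min <= pos <= b_max:
            return 0
        return min(abs(pos - b_min), abs(pos - b_max))

    offsets: list[int] = []
    matched_truth = [False] * len(truths)
    matched_det = [False] * len(detected)
    for ti, truth in enumerate(truths):
        best: tuple[int, int] | None = None
        for di, det in enumerate(detected):
            if truth["acceptor"] not in det.triplet or truth["donor"] not in det.triplet:
                continue
            pos = det.positions.get(truth["acceptor"])
            if pos is None:
                continue
            off = _offset(truth, pos)
            if off <= tolerance_nt and (best is None or off < best[0]):
                best = (off, di)
        if best is not None:
            matched_truth[ti] = True
            matched_det[best[1]] = True
            offsets.append(best[0])
    # any detection matching *some* truth within tolerance counts toward precision
    for di, det in enumerate(detected):
        if matched_det[di]:
            continue
        for truth in truths:
            if truth["acceptor"] in det.triplet and truth["donor"] in det.triplet:
                pos = det.positions.get(truth["acceptor"])
                if pos is not None and _offset(truth, pos) <= tolerance_nt:
                    matched_det[di] = True
                    break
    recall = sum(matched_truth) / len(truths) if truths else 1.0
    if not detected:
        return RecoveryResult(1.0, recall, offsets, len(truths), 0, zero_predictions=True)
    precision = sum(matched_det) / len(detected)
    return RecoveryResult(precision, recall, offsets, len(truths), len(detected))


def write_event_log(family: SimulatedFamily, path: str) -> None:
    with open(path, "w") as handle:
        handle.write("kind\tdetail\n")
        for event in family.event_log:
            detail = ";".join(f"{k}={v}" for k, v in event.detail.items())
            handle.write(f"{event.kind}\t{detail}\n")
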