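"""Domain-context evidence: gene-fusion association (CODA) and
per-domain over-representation (DORA).

CODA ("co-occurrence of domains") infers a functional link between two
proteins p, q of a query genome when a superfamily a carried by p and a
superfamily b carried by q are found fused into a single protein r of
some other (target) genome — the classic Rosetta-stone argument.  The
pair-level score is a double maximum: over the candidate domain pairs
J_{p,q} and, within a domain pair, over the fusion genomes T.

DORA scores a single superfamily by the ratio of its relative frequency
in a target set of proteins (e.g. the known-spindle set) to its
relative frequency in the whole genome; a protein inherits the best
score over its superfamilies.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable

from .core import NoScore, ReferenceSet, ScoredPair, TargetScoreList, collapse_pairs

DomainPair = tuple[str, str]  # sorted superfamily pair


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered superfamily composition of one protein in one genome.

    Order is preserved in the data model but ignored by the scorers,
    which are set-based; the same superfamily may appear repeatedly.
    """

    genome: str
    protein: str
    superfamilies: tuple[str, ...]

    def families(self) -> frozenset[str]:
        return frozenset(self.superfamilies)


@dataclass
class ArchitectureTable:
    """Domain architectures across genomes, with per-genome frequency counts."""

    by_genome: dict[str, dict[str, DomainArchitecture]] = field(default_factory=dict)

    @classmethod
    def from_architectures(
        cls, archs: Iterable[DomainArchitecture]
    ) -> "ArchitectureTable":
        table = cls()
        for a in archs:
            genome = table.by_genome.setdefault(a.genome, {})
            if a.protein in genome:
                raise ValueError(
                    f"duplicate architecture for {a.protein!r} in genome {a.genome!r}"
                )
            genome[a.protein] = a
        return table

    def genomes(self) -> list[str]:
        return sorted(self.by_genome)

    def architecture(self, genome: str, protein: str) -> DomainArchitecture:
        try:
            return self.by_genome[genome][protein]
        except KeyError:
            raise KeyError(f"no architecture for {protein!r} in genome {genome!r}")

    def genome_frequencies(self, genome: str) -> Counter:
        """Occurrence count of every superfamily in one genome (f^g_a).

        Repeats within an architecture each count as an occurrence.
        """
        counts: Counter = Counter()
        for arch in self.by_genome.get(genome, {}).values():
            counts.update(arch.superfamilies)
        return counts

    def fusion_index(self, query_genome: str) -> dict[DomainPair, set[str]]:
        """Map each sorted domain pair to the set T of non-query genomes
        containing a protein whose architecture fuses both domains."""
        index: dict[DomainPair, set[str]] = defaultdict(set)
        for genome, prots in self.by_genome.items():
            if genome == query_genome:
                continue
            for arch in prots.values():
                fams = sorted(arch.families())
                for i, a in enumerate(fams):
                    for b in fams[i + 1 :]:
                        index[(a, b)].add(genome)
        return dict(index)


def domain_pairs(p: DomainArchitecture, q: DomainArchitecture) -> set[DomainPair]:
    """J_{p,q}: all distinct cross pairs {a, b}, a in D_p, b in D_q, a != b.

    With D_p = {a, c} and D_q = {b} this yields {ab, cb}.
    """
    pairs: set[DomainPair] = set()
    for a in p.families():
        for b in q.families():
            if a != b:
                pairs.add(tuple(sorted((a, b))))
    return pairs


# Registered fusion-score forms: f(T_size, f_g_a, f_g_b, f_t_a, f_t_b).
CODA_FORMS: dict[str, Callable[[int, int, int, int, int], float]] = {
    "default": lambda T, fga, fgb, fta, ftb: T / (fga * fgb * fta * ftb),
}


@dataclass
class CodaScorer:
    """Precomputes frequencies and the fusion index for one query genome."""

    table: ArchitectureTable
    query_genome: str
    form: str = "default"

    def __post_init__(self) -> None:
        if self.query_genome not in self.table.by_genome:
            raise ValueError(f"query genome {self.query_genome!r} not in table")
        self._freqs = {g: self.table.genome_frequencies(g) for g in self.table.genomes()}
        self._fusions = self.table.fusion_index(self.query_genome)
        self._form = CODA_FORMS[self.form]
        self._pair_cache: dict[DomainPair, float | None] = {}

    def domain_pair_score(self, a: str, b: str) -> float | None:
        """s_{a,b}: best fusion score over target genomes, None when T is empty."""
        key: DomainPair = tuple(sorted((a, b)))
        if key in self._pair_cache:
            return self._pair_cache[key]
        T = self._fusions.get(key, set())
        if not T:
            self._pair_cache[key] = None
            return None
        fg = self._freqs[self.query_genome]
        best = max(
            self._form(len(T), fg[key[0]], fg[key[1]], self._freqs[t][key[0]], self._freqs[t][key[1]])
            for t in T
        )
        self._pair_cache[key] = best
        return best

    def pair_score(self, p: str, q: str) -> float | None:
        """s_{p,q}: best s_{a,b} over J_{p,q}; None when no pair scores.

        Protein pairs sharing any superfamily are excluded entirely
        (shared domains make the fusion argument circular).
        """
        if p == q:
            raise ValueError("CODA is defined for distinct proteins")
        ap = self.table.architecture(self.query_genome, p)
        aq = self.table.architecture(self.query_genome, q)
        if ap.families() & aq.families():
            return None
        best: float | None = None
        for a, b in domain_pairs(ap, aq):
            s = self.domain_pair_score(a, b)
            if s is not None and (best is None or s > best):
                best = s
        return best


def coda_pair_score(
    p: str,
    q: str,
    table: ArchitectureTable,
    query_genome: str,
    form: str = "default",
) -> float | None:
    """One-shot CODA score; prefer CodaScorer for repeated calls."""
    return CodaScorer(table, query_genome, form).pair_score(p, q)


@dataclass(frozen=True)
class DoraTable:
    """Frequency quadruple for one superfamily.

    Ft/Nt: occurrences of the family in the target set over total
    domains in the target set; Fb/Nb: same over the whole genome.
    """

    Ft: int
    Nt: int
    Fb: int
    Nb: int

    def __post_init__(self) -> None:
        if self.Nt <= 0 or self.Nb <= 0:
            raise ValueError("Nt and Nb must be positive")
        if self.Ft > self.Fb or self.Nt > self.Nb:
            raise ValueError("target counts cannot exceed background counts")
        if min(self.Ft, self.Fb) < 0:
            raise ValueError("negative counts")


def dora_score(t: DoraTable) -> float:
    """C_ij = (Ft/Nt) / (Fb/Nb): relative-frequency enrichment of a family."""
    if t.Fb == 0:
        raise NoScore("family absent from the background genome")
    return (t.Ft / t.Nt) / (t.Fb / t.Nb)


def build_dora_tables(
    table: ArchitectureTable, genome: str, target_set: Iterable[str]
) -> dict[str, DoraTable]:
    """Per-family DORA tables from a genome scan against a target protein set."""
    targets = set(target_set)
    bg = table.genome_frequencies(genome)
    Nb = sum(bg.values())
    fg: Counter = Counter()
    for pid in targets:
        arch = table.by_genome.get(genome, {}).get(pid)
        if arch is not None:
            fg.update(arch.superfamilies)
    Nt = sum(fg.values())
    if Nt == 0:
        return {}
    return {
        fam: DoraTable(Ft=fg.get(fam, 0), Nt=Nt, Fb=bg[fam], Nb=Nb) for fam in bg
    }


def coda_all_pairs(
    table: ArchitectureTable,
    query_genome: str,
    reference: ReferenceSet,
    method: str = "CODA",
    form: str = "default",
) -> list[ScoredPair]:
    """All scorable (bait, candidate) fusion-association pairs."""
    scorer = CodaScorer(table, query_genome, form)
    prots = table.by_genome[query_genome]
    baits = [b for b in sorted(reference.members) if b in prots]
    pairs: list[ScoredPair] = []
    for b in baits:
        for t in prots:
            if t in reference.members:
                continue
            s = scorer.pair_score(b, t)
            if s is not None:
                pairs.append(ScoredPair(b, t, method, s))
    return pairs


def score_all_coda(
    table: ArchitectureTable,
    query_genome: str,
    reference: ReferenceSet,
    method: str = "CODA",
    form: str = "default",
) -> TargetScoreList:
    """Fusion-association channel: best CODA score of each candidate
    against any reference bait, collapsed per target."""
    out = collapse_pairs(
        coda_all_pairs(table, query_genome, reference, method, form),
        higher_is_better=True,
    )
    out.method = method
    out.metadata["form"] = form
    return out


def score_all_dora(
    table: ArchitectureTable,
    query_genome: str,
    reference: ReferenceSet,
) -> TargetScoreList:
    """Domain over-representation channel: best family enrichment per protein."""
    tables = build_dora_tables(table, query_genome, reference.members)
    out = TargetScoreList(method="DORA")
    for pid, arch in table.by_genome[query_genome].items():
        if pid in reference.members:
            continue
        try:
            s = dora_protein_score(arch, tables)
        except NoScore:
            continue
        if s > 0:
            out.scores[pid] = s
    return out


def dora_protein_score(
    arch: DomainArchitecture, tables: dict[str, DoraTable]
) -> float:
    """Best C_ij over the protein's families; NoScore when none is scorable."""
    scores = [
        dora_score(tables[f]) for f in arch.families() if f in tables
    ]
    if not scores:
        raise NoScore(f"no scorable family for {arch.protein!r}")
    return max(scores)
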