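"""Seeded synthetic benchmark generator.

Produces every input the platform consumes — co-citation network,
domain architectures for a query genome plus fusion-bearing target
genomes under two independent annotation vocabularies, family
clustering with known interactions, an expression compendium, an
annotation ontology, a protein feature table with labels and a
similarity matrix — with a planted positive module whose members carry
correlated signal in all evidence channels.  A subset of the module
seeds the scorers (the SEED-like reference) and a disjoint held-out
subset (EXPERT-like) is reserved for benchmarking, so end-to-end
recovery can be measured without any external download.

Presets: ``default`` (signal at the study conditions), ``null`` (no
planted signal anywhere: the module is only a label set, every channel
sees exchangeable noise) and ``strong`` (sharper signal for quick
demos).  A bundle regenerated with the same parameters and seed is
byte-identical, which the content hash makes checkable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as spio
from .cocite import CocitationNetwork
from .core import ProteomeRegistry, ReferenceSet
from .domains import ArchitectureTable, DomainArchitecture
from .goss import AnnotationDAG
from .hippi import FamilyClustering, KnownInteraction, N_LEVELS
from .hubs import EvidenceGraph, build_kg

QUERY_GENOME = "query"


@dataclass(frozen=True)
class FixtureParams:
    """Generation parameters; defaults are the benchmark study conditions.

    The proteome-to-module scale (500:40, with 25 seeds) mirrors a
    ~0.5% positive rate at desk scale.  ``p_in``/``p_out`` are the
    within-module and background co-citation edge probabilities,
    ``rho`` the module co-expression correlation, ``effect`` the
    informative-feature shift in SD units.
    """

    n: int = 500
    m: int = 40
    seed_size: int = 25
    holdout_size: int = 15
    p_in: float = 0.25
    p_out: float = 0.02
    physical_rate: float = 0.8
    n_target_genomes: int = 4
    n_superfamilies: int = 150
    n_module_superfamilies: int = 8
    rho: float = 0.7
    n_conditions: int = 40
    missing_rate: float = 0.02
    n_branches: int = 12
    n_mids_per_branch: int = 6
    n_leaves_per_mid: int = 8
    n_features: int = 20
    n_informative: int = 4
    effect: float = 1.5
    n_neg_labels: int = 90
    n_module_known: int = 30
    n_background_known: int = 40
    preset: str = "default"

    def validate(self) -> None:
        if self.n < 50:
            raise ValueError("n must be >= 50")
        if not 10 <= self.m <= self.n:
            raise ValueError("m must be in [10, n]")
        if self.seed_size + self.holdout_size > self.m:
            raise ValueError("seed + holdout larger than module")
        if self.p_in < self.p_out:
            raise ValueError("p_in below p_out is contradictory signal")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")


def preset_params(preset: str = "default") -> FixtureParams:
    base = FixtureParams()
    if preset == "default":
        return base
    if preset == "null":
        return replace(
            base, preset="null", p_in=base.p_out, rho=0.0, effect=0.0
        )
    if preset == "strong":
        return replace(base, preset="strong", p_in=0.4, rho=0.85, effect=2.5)
    raise ValueError(f"unknown preset {preset!r}")


@dataclass
class BenchmarkBundle:
    """Everything a full platform run needs, plus the planted truth."""

    params: FixtureParams
    seed: int
    registry: ProteomeRegistry
    module: list[str]
    seed_set: ReferenceSet
    expert_set: ReferenceSet
    cocitation: CocitationNetwork
    arch_cath: ArchitectureTable
    arch_pfam: ArchitectureTable
    clustering: FamilyClustering
    known_interactions: list[KnownInteraction]
    expression: pd.DataFrame
    dag_edges: list[tuple[str, str]]
    annotations: dict[str, set[str]]
    features: pd.DataFrame
    labels: pd.Series
    similarity: pd.DataFrame
    kg_sources: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def dag(self) -> AnnotationDAG:
        return AnnotationDAG.build(self.dag_edges, self.annotations)

    def serialized_parts(self) -> dict[str, str]:
        """Canonical text rendering of every component (also what
        write_bundle puts on disk)."""
        edges = [
            (u, v, d["relation"])
            for u, v, d in self.cocitation.graph.edges(data=True)
        ]
        parts = {
            "params.json": json.dumps(
                {"seed": self.seed, **asdict(self.params)}, sort_keys=True
            )
            + "\n",
            "registry.txt": spio.serialize(
                spio.write_id_list, sorted(self.registry.proteins)
            ),
            "module.txt": spio.serialize(spio.write_id_list, self.module),
            "seed_set.txt": spio.serialize(
                spio.write_id_list, sorted(self.seed_set.members)
            ),
            "expert_set.txt": spio.serialize(
                spio.write_id_list, sorted(self.expert_set.members)
            ),
            "cocitation.tsv": spio.serialize(spio.write_edge_tsv, edges),
            "arch_cath.tsv": spio.serialize(
                spio.write_architecture_tsv, self.arch_cath
            ),
            "arch_pfam.tsv": spio.serialize(
                spio.write_architecture_tsv, self.arch_pfam
            ),
            "clustering.tsv": spio.serialize(
                spio.write_clustering_tsv, self.clustering
            ),
            "known_interactions.tsv": spio.serialize(
                spio.write_known_interactions_tsv, self.known_interactions
            ),
            "expression.tsv": spio.serialize(
                spio.write_matrix_tsv, self.expression
            ),
            "dag.tsv": spio.serialize(spio.write_dag_tsv, self.dag_edges),
            "annotations.tsv": spio.serialize(
                spio.write_annotations_tsv, self.annotations
            ),
            "features.tsv": spio.serialize(
                lambda obj, buf: spio.write_matrix_tsv(obj, buf, index_name="protein"),
                self.features,
            ),
            "labels.tsv": spio.serialize(spio.write_labels_tsv, self.labels),
            "similarity.tsv": spio.serialize(
                lambda obj, buf: spio.write_matrix_tsv(obj, buf, index_name="protein"),
                self.similarity,
            ),
            "kg_edges.tsv": spio.serialize(
                spio.write_untagged_edges,
                sorted(e for edges_ in self.kg_sources.values() for e in edges_),
            ),
        }
        return parts

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for name, text in sorted(self.serialized_parts().items()):
            h.update(name.encode())
            h.update(text.encode())
        return h.hexdigest()


def _gen_cocitation(rng, proteins, module_set, p):
    n = len(proteins)
    idx_mod = np.array([pid in module_set for pid in proteins])
    iu, ju = np.triu_indices(n, k=1)
    both_mod = idx_mod[iu] & idx_mod[ju]
    probs = np.where(both_mod, p.p_in, p.p_out)
    draws = rng.random(len(probs))
    physical = rng.random(len(probs)) < p.physical_rate
    edges = []
    prot = np.asarray(proteins)
    for k in np.nonzero(draws < probs)[0]:
        rel = "physical" if physical[k] else "genetic"
        edges.append((str(prot[iu[k]]), str(prot[ju[k]]), rel))
    return CocitationNetwork.from_edges(edges)


def _popularity(n: int, exponent: float) -> "np.ndarray":
    # power-law popularity so occurrence counts, and hence frequency-based
    # scores, are dispersed the way real domain/term usage is
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def _gen_architectures(rng, proteins, module, planted, p, tag):
    bg_vocab = [f"{tag}SF{i:03d}" for i in range(p.n_superfamilies)]
    mod_vocab = [f"{tag}MSF{i:02d}" for i in range(p.n_module_superfamilies)]
    weights = _popularity(p.n_superfamilies, 0.4)
    module_set = set(module) if planted else set()
    archs = []
    for pid in proteins:
        k = int(rng.integers(1, 4))
        sfs = [str(s) for s in rng.choice(bg_vocab, size=k, replace=False, p=weights)]
        if pid in module_set:
            msf = [str(s) for s in rng.choice(mod_vocab, size=min(2, k), replace=False)]
            sfs[: len(msf)] = msf
        archs.append(DomainArchitecture(QUERY_GENOME, pid, tuple(sfs)))
    genomes = [f"T{i+1}" for i in range(p.n_target_genomes)]
    # background content of target genomes: defines target-genome frequencies
    for g in genomes:
        for j in range(p.n // 2):
            k = int(rng.integers(1, 3))
            sfs = tuple(
                str(s) for s in rng.choice(bg_vocab, size=k, replace=False, p=weights)
            )
            archs.append(DomainArchitecture(g, f"{g}_{tag}{j:04d}", sfs))
    # planted fusions: module superfamily pairs fused in target genomes
    fusion_j = 0
    if planted:
        for i, a in enumerate(mod_vocab):
            for b in mod_vocab[i + 1 :]:
                if rng.random() < 0.5:
                    for g in rng.choice(genomes, size=int(rng.integers(1, 3)), replace=False):
                        archs.append(
                            DomainArchitecture(str(g), f"{g}_{tag}fuse{fusion_j:03d}", (a, b))
                        )
                        fusion_j += 1
    # background fusions keep the channel's null score distribution populated
    for _ in range(p.n // 3):
        a, b = (str(s) for s in rng.choice(bg_vocab, size=2, replace=False, p=weights))
        g = genomes[int(rng.integers(0, len(genomes)))]
        archs.append(DomainArchitecture(g, f"{g}_{tag}fuse{fusion_j:03d}", (a, b)))
        fusion_j += 1
    return ArchitectureTable.from_architectures(archs)


def _positions_to_levels(pos: float) -> tuple[str, ...]:
    # binary refinement: nested by construction, level 1 is the family
    return tuple(str(int(pos * 2 ** (lvl - 1))) for lvl in range(1, N_LEVELS + 1))


def _gen_clustering(rng, proteins, module, planted, p):
    clustering = FamilyClustering()
    if planted:
        mod_order = [str(x) for x in rng.permutation(module)]
        rest = [pid for pid in proteins if pid not in set(module)]
    else:
        mod_order = []
        rest = list(proteins)
    rest = [str(x) for x in rng.permutation(rest)]
    fam_i = 0
    # module families: 6-7 members, tight positions -> high shared S-levels
    while mod_order:
        members, mod_order = mod_order[:7], mod_order[7:]
        base = rng.random() * 0.9
        for pid in members:
            pos = base + rng.random() * 0.008
            clustering.add(pid, f"FM{fam_i:03d}", _positions_to_levels(pos))
        fam_i += 1
    while rest:
        size = int(rng.integers(3, 6))
        members, rest = rest[:size], rest[size:]
        base = rng.random() * 0.9
        for pid in members:
            pos = base + rng.random() * 0.1
            clustering.add(pid, f"FB{fam_i:03d}", _positions_to_levels(pos))
        fam_i += 1
    return clustering


def _gen_known_interactions(rng, proteins, seeds, planted, p):
    evidence_pool = ["y2h", "coip", "ms", "tap"]
    species_pool = ["hsapiens", "mmusculus", "scerevisiae"]
    known = []

    def sample(pool_a, pool_b, count):
        for _ in range(count):
            a = pool_a[int(rng.integers(0, len(pool_a)))]
            b = pool_b[int(rng.integers(0, len(pool_b)))]
            if a == b:
                continue
            n_ev = int(rng.integers(1, 3))
            n_sp = int(rng.integers(1, 3))
            known.append(
                KnownInteraction(
                    a,
                    b,
                    frozenset(map(str, rng.choice(evidence_pool, size=n_ev, replace=False))),
                    frozenset(map(str, rng.choice(species_pool, size=n_sp, replace=False))),
                )
            )

    if planted:
        sample(list(seeds), list(seeds), p.n_module_known)
    sample(list(proteins), list(proteins), p.n_background_known)
    return known


def _gen_expression(rng, proteins, module_set, p):
    conditions = [f"C{i:03d}" for i in range(p.n_conditions)]
    latent = rng.standard_normal(p.n_conditions)
    rows = {}
    for pid in proteins:
        noise = rng.standard_normal(p.n_conditions)
        if pid in module_set and p.rho > 0:
            x = np.sqrt(p.rho) * latent + np.sqrt(1 - p.rho) * noise
        else:
            x = noise
        mask = rng.random(p.n_conditions) < p.missing_rate
        x = x.copy()
        x[mask] = np.nan
        rows[pid] = x
    return pd.DataFrame.from_dict(rows, orient="index", columns=conditions).round(6)


def _gen_ontology(rng, proteins, module_set, p):
    root = "T:ROOT"
    edges = []
    leaves_by_branch: dict[int, list[str]] = {}
    for b in range(p.n_branches):
        branch = f"T:B{b}"
        edges.append((branch, root))
        leaves_by_branch[b] = []
        for mlevel in range(p.n_mids_per_branch):
            mid = f"T:B{b}.M{mlevel}"
            edges.append((mid, branch))
            for l in range(p.n_leaves_per_mid):
                leaf = f"T:B{b}.M{mlevel}.L{l}"
                edges.append((leaf, mid))
                leaves_by_branch[b].append(leaf)
    all_leaves = [l for ls in leaves_by_branch.values() for l in ls]
    weights = _popularity(len(all_leaves), 0.4)
    spindle_leaves = leaves_by_branch[0][: 2 * p.n_leaves_per_mid]
    annotations: dict[str, set[str]] = {}
    for pid in proteins:
        k = int(rng.integers(3, 8))
        terms = [str(t) for t in rng.choice(all_leaves, size=k, replace=False, p=weights)]
        if pid in module_set:
            n_spindle = int(rng.integers(1, 3))
            planted = [str(t) for t in rng.choice(spindle_leaves, size=n_spindle, replace=False)]
            terms = planted + terms[: k - n_spindle]
        annotations[pid] = set(terms)
    return edges, annotations


def _gen_features(rng, proteins, module_set, p):
    cols = [f"f{i:02d}" for i in range(p.n_features)]
    X = rng.standard_normal((len(proteins), p.n_features))
    is_mod = np.array([pid in module_set for pid in proteins])
    X[is_mod, : p.n_informative] += p.effect
    features = pd.DataFrame(X, index=list(proteins), columns=cols).round(6)
    return features


def _gen_labels_similarity(rng, seeds, background, p):
    negatives = sorted(str(b) for b in rng.choice(background, size=p.n_neg_labels, replace=False))
    labels = pd.Series(
        {**{s: 1 for s in sorted(seeds)}, **{b: 0 for b in negatives}},
        name="label",
        dtype=int,
    )
    ids = sorted(labels.index)
    k = len(ids)
    sim = rng.random((k, k)) * 0.25
    sim = (sim + sim.T) / 2
    np.fill_diagonal(sim, 1.0)
    similarity = pd.DataFrame(sim, index=ids, columns=ids)
    # a few near-duplicate pairs so homology reduction has work to do
    neg_ids = [i for i in ids if labels[i] == 0]
    for _ in range(6):
        a, b = (str(x) for x in rng.choice(neg_ids, size=2, replace=False))
        similarity.loc[a, b] = similarity.loc[b, a] = 0.9
    return labels, similarity.round(6)


def generate(params: FixtureParams | None = None, seed: int = 0) -> BenchmarkBundle:
    """Generate a full benchmark bundle; identical (params, seed) pairs
    produce byte-identical bundles."""
    p = params or FixtureParams()
    p.validate()
    planted = p.preset != "null"
    rng = np.random.default_rng(seed)

    proteins = [f"P{i:04d}" for i in range(p.n)]
    module = sorted(str(x) for x in rng.choice(proteins, size=p.m, replace=False))
    order = [str(x) for x in rng.permutation(module)]
    seeds = sorted(order[: p.seed_size])
    holdout = sorted(order[p.seed_size : p.seed_size + p.holdout_size])
    module_set = set(module) if planted else set()
    background = sorted(set(proteins) - set(module))

    registry = ProteomeRegistry.from_ids(proteins)
    seed_set = ReferenceSet.from_ids("SEED", seeds)
    expert_set = ReferenceSet.from_ids("EXPERT", holdout)

    cocitation = _gen_cocitation(rng, proteins, set(module), p)
    arch_cath = _gen_architectures(rng, proteins, module, planted, p, "c")
    arch_pfam = _gen_architectures(rng, proteins, module, planted, p, "p")
    clustering = _gen_clustering(rng, proteins, module, planted, p)
    known = _gen_known_interactions(rng, proteins, seeds, planted, p)
    expression = _gen_expression(rng, proteins, module_set, p)
    dag_edges, annotations = _gen_ontology(rng, proteins, module_set, p)
    features = _gen_features(rng, proteins, module_set, p)
    labels, similarity = _gen_labels_similarity(rng, seeds, background, p)

    kg_edges = sorted(
        {tuple(sorted((k.a, k.b))) for k in known}
    )
    bundle = BenchmarkBundle(
        params=p,
        seed=seed,
        registry=registry,
        module=module,
        seed_set=seed_set,
        expert_set=expert_set,
        cocitation=cocitation,
        arch_cath=arch_cath,
        arch_pfam=arch_pfam,
        clustering=clustering,
        known_interactions=known,
        expression=expression,
        dag_edges=dag_edges,
        annotations=annotations,
        features=features,
        labels=labels,
        similarity=similarity,
        kg_sources={"known": [tuple(e) for e in kg_edges]},
    )
    return bundle


def write_bundle(bundle: BenchmarkBundle, directory: str | Path) -> dict[str, str]:
    """Write every component to ``directory``; returns a checksum manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, text in sorted(bundle.serialized_parts().items()):
        (directory / name).write_text(text, encoding="utf-8")
        manifest[name] = hashlib.sha256(text.encode()).hexdigest()
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
    )
    return manifest


def verify_bundle(directory: str | Path) -> list[str]:
    """Names of files whose checksum no longer matches the manifest."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    bad = []
    for name, digest in manifest.items():
        text = (directory / name).read_text(encoding="utf-8")
        if hashlib.sha256(text.encode()).hexdigest() != digest:
            bad.append(name)
    return bad


def read_bundle(directory: str | Path) -> BenchmarkBundle:
    """Reload a bundle written by write_bundle."""
    d = Path(directory)
    meta = json.loads((d / "params.json").read_text())
    seed = meta.pop("seed")
    params = FixtureParams(**meta)
    registry = ProteomeRegistry.from_ids(spio.read_id_list(d / "registry.txt"))
    return BenchmarkBundle(
        params=params,
        seed=seed,
        registry=registry,
        module=spio.read_id_list(d / "module.txt"),
        seed_set=ReferenceSet.from_ids("SEED", spio.read_id_list(d / "seed_set.txt")),
        expert_set=ReferenceSet.from_ids(
            "EXPERT", spio.read_id_list(d / "expert_set.txt")
        ),
        cocitation=spio.read_cocitation_network(d / "cocitation.tsv"),
        arch_cath=spio.read_architecture_tsv(d / "arch_cath.tsv"),
        arch_pfam=spio.read_architecture_tsv(d / "arch_pfam.tsv"),
        clustering=spio.read_clustering_tsv(d / "clustering.tsv"),
        known_interactions=spio.read_known_interactions_tsv(
            d / "known_interactions.tsv"
        ),
        expression=spio.read_matrix_tsv(d / "expression.tsv"),
        dag_edges=spio.read_dag_tsv(d / "dag.tsv"),
        annotations=spio.read_annotations_tsv(d / "annotations.tsv"),
        features=spio.read_matrix_tsv(d / "features.tsv", index_name="protein"),
        labels=spio.read_labels_tsv(d / "labels.tsv"),
        similarity=spio.read_matrix_tsv(d / "similarity.tsv", index_name="protein"),
        kg_sources={"known": spio.read_untagged_edges(d / "kg_edges.tsv")},
    )


def hub_scenario(seed: int = 0, n_spindle: int = 30, n_background: int = 40):
    """Small network scenario with one planted hidden hub.

    The hub has almost no experimentally known edges but many predicted
    edges, nearly all into the known-spindle set; decoys either have
    plenty of KG support or unspecific PG neighbourhoods.  Returns
    (kg, pg, spindle_set, candidates).
    """
    rng = np.random.default_rng(seed)
    spindle = [f"S{i:03d}" for i in range(n_spindle)]
    others = [f"B{i:03d}" for i in range(n_background)]
    hub = "HUB00"
    known_hub = "KNOWN0"  # well-characterised hub: high KG degree, excluded
    sticky = "STICKY"     # many PG edges but unspecific to the spindle set
    candidates = [hub, known_hub, sticky] + others[:5]

    kg_edges = [(known_hub, s) for s in spindle[:20]]
    kg_edges += [(hub, spindle[0])]
    kg_edges += [(others[i], others[i + 1]) for i in range(0, 20, 2)]
    kg = build_kg({"experimental": kg_edges})

    pg_edges = [(hub, s) for s in spindle[:24]] + [(hub, others[0])]
    pg_edges += [(known_hub, s) for s in spindle[:22]]
    pg_edges += [(sticky, o) for o in others[: 25]] + [(sticky, spindle[0])]
    for c in others[:5]:
        partners = [str(x) for x in rng.choice(spindle + others, size=3, replace=False)]
        pg_edges += [(c, p) for p in partners if p != c]
    pg = EvidenceGraph.from_sources("PG", {"predicted": pg_edges})
    return kg, pg, set(spindle), candidates
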