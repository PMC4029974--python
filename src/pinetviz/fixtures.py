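"""Synthetic datasets: the canonical 6-protein toy network and a
deterministic random-network generator.

The toy network (``toy6``) is the worked example used throughout the
documentation and tests: two organisms ("A": P1-P3, "B": P4-P6), five
scored interactions forming a triangle bridged to a path, one isolated
protein (P6), and a single STRING evidence score on the bridge edge
P3-P4.

``generate`` emulates the shape of multi-organism PPI datasets (organism
blocks, sparse within-organism edges, rarer cross-organism edges,
patchy per-source evidence) without any biological realism in degree
distributions — it exists to exercise parsers, queries and layouts at
controlled sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from ._rng import PortableRandom
from .errors import PinvError
from .io import Dataset, load_dataset

__all__ = ["toy6", "GeneratorSpec", "generate", "generate_dataset"]

_DEFAULT_VOCAB = {
    "description": [
        "kinase",
        "Sensor histidine kinase",
        "transporter",
        "regulator",
        "membrane protein",
        "hydrolase",
    ],
    "functional_class": ["metabolism", "signalling", "transport", "unknown"],
}


def _read_data(name: str) -> str:
    return (resources.files("pinetviz") / "data" / name).read_text(encoding="utf-8")


def toy6(with_expression: bool = False) -> Dataset:
    """The fixed 6-protein, 5-interaction toy dataset.

    Proteins P1-P3 belong to organism "A", P4-P6 to "B"; P6 has no
    interactions.  ``with_expression=True`` additionally attaches the
    two-condition expression matrix used by the quantitative-coloring
    examples.
    """
    return load_dataset(
        _read_data("toy6_interactions.tsv"),
        _read_data("toy6_features.tsv"),
        _read_data("toy6_expression.tsv") if with_expression else None,
    )


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic dataset generator.

    ``organisms`` is a list of (name, proportion) pairs; proportions must
    sum to 1.  Edges within an organism block are sampled independently
    with ``edge_probability``; edges across blocks with
    ``cross_organism_probability``.  Scores are uniform in (0, 1]; each
    evidence cell is present with probability 0.5.
    """

    n_proteins: int = 60
    organisms: list[tuple[str, float]] = field(
        default_factory=lambda: [("ORG1", 0.5), ("ORG2", 0.5)]
    )
    edge_probability: float = 0.08
    cross_organism_probability: float = 0.02
    n_evidence_sources: int = 2
    feature_vocab: dict[str, list[str]] = field(default_factory=lambda: dict(_DEFAULT_VOCAB))
    n_conditions: int = 2
    seed: int = 1

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise PinvError("n_proteins must be >= 1")
        if not self.organisms:
            raise PinvError("at least one organism is required")
        total = sum(p for _, p in self.organisms)
        if abs(total - 1.0) > 1e-9:
            raise PinvError(f"organism proportions must sum to 1, got {total!r}")
        for prob, name in [
            (self.edge_probability, "edge_probability"),
            (self.cross_organism_probability, "cross_organism_probability"),
        ]:
            if not 0.0 <= prob <= 1.0:
                raise PinvError(f"{name} must be in [0, 1]")


def _block_sizes(spec: GeneratorSpec) -> list[int]:
    """Largest-remainder apportionment of n_proteins across organisms."""
    raw = [spec.n_proteins * p for _, p in spec.organisms]
    sizes = [int(r) for r in raw]
    remainders = sorted(
        range(len(raw)), key=lambda i: (-(raw[i] - sizes[i]), i)
    )
    for i in range(spec.n_proteins - sum(sizes)):
        sizes[remainders[i % len(raw)]] += 1
    return sizes


def generate(spec: GeneratorSpec) -> tuple[str, str, str]:
    """Generate (interactions TSV, features TSV, expression TSV) texts.

    Deterministic for a fixed ``spec.seed``; the emitted files parse
    through :mod:`pinetviz.io` with zero warnings.
    """
    spec.validate()
    rng = PortableRandom(spec.seed)
    width = len(str(spec.n_proteins))
    sizes = _block_sizes(spec)

    accessions: list[str] = []
    organism_of: dict[str, str] = {}
    k = 0
    for (org, _), size in zip(spec.organisms, sizes):
        for _ in range(size):
            k += 1
            acc = f"P{k:0{width}d}"
            accessions.append(acc)
            organism_of[acc] = org

    feature_names = list(spec.feature_vocab)
    feat_lines = ["\t".join(["accession", "organism"] + feature_names)]
    for acc in accessions:
        cells = [acc, organism_of[acc]]
        for name in feature_names:
            cells.append(rng.choice(spec.feature_vocab[name]))
        feat_lines.append("\t".join(cells))

    ev_names = [f"source{i + 1}" for i in range(spec.n_evidence_sources)]
    inter_lines = ["\t".join(["protein_a", "protein_b", "score"] + ev_names)]
    for i in range(len(accessions)):
        for j in range(i + 1, len(accessions)):
            a, b = accessions[i], accessions[j]
            same = organism_of[a] == organism_of[b]
            p = spec.edge_probability if same else spec.cross_organism_probability
            if rng.random() >= p:
                continue
            score = 1.0 - rng.random()  # uniform (0, 1]
            cells = [a, b, f"{score:.6f}"]
            for _ in ev_names:
                if rng.random() < 0.5:
                    cells.append(f"{1.0 - rng.random():.6f}")
                else:
                    cells.append("")
            inter_lines.append("\t".join(cells).rstrip("\t"))

    conditions = [f"condition{i + 1}" for i in range(spec.n_conditions)]
    expr_lines = ["\t".join(["id"] + conditions)]
    for acc in accessions:
        cells = [acc] + [f"{rng.uniform(0.0, 10.0):.4f}" for _ in conditions]
        expr_lines.append("\t".join(cells))

    return (
        "\n".join(inter_lines) + "\n",
        "\n".join(feat_lines) + "\n",
        "\n".join(expr_lines) + "\n",
    )


def generate_dataset(spec: GeneratorSpec, with_expression: bool = False) -> Dataset:
    """Generate and immediately parse a synthetic dataset."""
    inter, feat, expr = generate(spec)
    return load_dataset(inter, feat, expr if with_expression else None)
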