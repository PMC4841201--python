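"""Synthetic genome communities with controlled word-usage structure.

Genomes are emitted by Markov chains over {A, C, G, T}. A *cluster* is a
shared order-3 transition model (the lowest order that directly shapes
4-mer usage); each member genome re-draws that model with a tight Dirichlet
jitter so within-cluster variance is nonzero but small, mimicking the
spread of genomes within a real subcluster. The generator can additionally
plant ground-truthed features:

* a horizontally-transferred segment — a contiguous block regenerated from
  a *different* cluster's model, replacing host sequence at a recorded
  position (length is preserved);
* a tandem-repeat block — ``copies`` copies of a unit string inserted at a
  recorded position (length grows by ``copies * len(unit)``).

Everything is deterministic given the spec's single seed: sub-seeds for
models, genomes and planted features are derived by fixed arithmetic, so
regenerating any part of a community is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence_io import Genome, ValidationError

MAX_ORDER = 5
_JITTER_CONCENTRATION = 500.0  # per-genome Dirichlet re-draw around the cluster model
_SEED_MOD = 2**31


def _subseed(seed: int, *tags: int) -> int:
    """Deterministic sub-seed from a top-level seed and integer tags."""
    out = seed % _SEED_MOD
    for t in tags:
        out = (out * 1_000_003 + t * 8191 + 12345) % _SEED_MOD
    return out


@dataclass
class BiasedModel:
    """Order-``order`` Markov model: one probability row per context.

    ``probs`` has shape (4**order, 4); row c gives P(next base | context c),
    contexts indexed by base-4 encoding with A=0, C=1, G=2, T=3.
    """

    order: int
    probs: np.ndarray
    model_id: str = "model"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        expected_shape = (4**self.order, 4)
        if self.probs.shape != expected_shape:
            raise ValidationError(
                f"probs shape {self.probs.shape} != {expected_shape} for order {self.order}"
            )
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-12):
            raise ValidationError("each context's probabilities must sum to 1")


def random_biased_model(
    order: int = 3, bias_strength: float = 0.5, seed: int = 0, model_id: str = "model"
) -> BiasedModel:
    """Draw a biased Markov model from a Dirichlet around the uniform model.

    Per-context probabilities are Dirichlet with concentration
    1/bias_strength in each of the four slots: bias_strength -> 0 recovers
    the uniform model, larger values give stronger (more idiosyncratic)
    word-usage signatures.
    """
    if not 0 <= order <= MAX_ORDER:
        raise ValidationError(f"order must be in [0, {MAX_ORDER}], got {order}")
    if bias_strength < 0:
        raise ValidationError(f"bias_strength must be >= 0, got {bias_strength}")
    n_contexts = 4**order
    if bias_strength == 0:
        probs = np.full((n_contexts, 4), 0.25)
    else:
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.full(4, 1.0 / bias_strength), size=n_contexts)
    return BiasedModel(order=order, probs=probs, model_id=model_id)


def jitter_model(model: BiasedModel, seed: int, concentration: float = _JITTER_CONCENTRATION) -> BiasedModel:
    """Re-draw each context row from a tight Dirichlet around the model."""
    rng = np.random.default_rng(seed)
    probs = np.vstack(
        [rng.dirichlet(np.maximum(row, 1e-6) * concentration) for row in model.probs]
    )
    return BiasedModel(order=model.order, probs=probs, model_id=f"{model.model_id}+jitter")


def _sample_sequence(model: BiasedModel, length: int, rng: np.random.Generator) -> str:
    order = model.order
    us = rng.random(length).tolist()
    cum = model.probs.cumsum(axis=1)[:, :3].tolist()  # per-context thresholds
    bases = "ACGT"
    out: list[str] = []
    ctx = 0
    mask = 4**order - 1 if order > 0 else 0
    for i in range(min(order, length)):  # initial context drawn uniformly
        b = min(int(us[i] * 4), 3)
        out.append(bases[b])
        ctx = ((ctx << 2) | b) & mask
    for i in range(len(out), length):
        u = us[i]
        row = cum[ctx]
        if u < row[0]:
            b = 0
        elif u < row[1]:
            b = 1
        elif u < row[2]:
            b = 2
        else:
            b = 3
        out.append(bases[b])
        if order > 0:
            ctx = ((ctx << 2) | b) & mask
    return "".join(out)


def generate_genome(model: BiasedModel, length: int, seed: int, genome_id: str = "synthetic") -> Genome:
    """Generate one genome by iterated conditional sampling from a model."""
    if length <= model.order:
        raise ValidationError(f"length must exceed model order {model.order}, got {length}")
    rng = np.random.default_rng(seed)
    return Genome(id=genome_id, sequence=_sample_sequence(model, length, rng))


@dataclass(frozen=True)
class HGTSpec:
    """Plant a foreign segment: sequence from ``donor_cluster``'s model
    replaces host sequence in ``fraction`` of ``recipient_cluster``'s genomes."""

    donor_cluster: int
    segment_length: int
    fraction: float
    recipient_cluster: int = 0


@dataclass(frozen=True)
class RepeatSpec:
    """Insert a tandem repeat block (``copies`` copies of ``unit``) into
    ``fraction`` of ``cluster``'s genomes."""

    unit: str
    copies: int
    fraction: float = 1.0
    cluster: int = 0


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one genome: its cluster and any planted feature."""

    genome_id: str
    cluster: int
    feature_type: str  # "hgt" | "repeat" | "none"
    start: int = -1  # 0-based half-open; -1/-1 when feature_type == "none"
    end: int = -1


@dataclass
class SyntheticCommunitySpec:
    """Generative parameters for a cluster-structured genome community."""

    n_clusters: int = 3
    genomes_per_cluster: int = 5
    genome_length: int = 50_000
    bias_strength: float = 0.5
    order: int = 3
    hgt: HGTSpec | None = None
    repeats: RepeatSpec | None = None
    seed: int = 0


def generate_community(spec: SyntheticCommunitySpec) -> tuple[list[Genome], list[TruthRecord]]:
    """Generate a labeled community with ground truth for planted features.

    One biased model per cluster (sub-seeded from ``spec.seed``); each
    genome samples from a jittered copy of its cluster model. Genome labels
    record the cluster; truth records give planted-feature coordinates in
    the emitted genome (0-based half-open).
    """
    if spec.n_clusters < 1 or spec.genomes_per_cluster < 1:
        raise ValidationError("n_clusters and genomes_per_cluster must be >= 1")
    if spec.hgt is not None:
        for attr in ("donor_cluster", "recipient_cluster"):
            c = getattr(spec.hgt, attr)
            if not 0 <= c < spec.n_clusters:
                raise ValidationError(f"{attr} {c} out of range [0, {spec.n_clusters})")
        if spec.hgt.donor_cluster == spec.hgt.recipient_cluster:
            raise ValidationError("HGT donor and recipient clusters must differ")
        if not 0 <= spec.hgt.fraction <= 1:
            raise ValidationError("HGT fraction must be in [0, 1]")
        if spec.hgt.segment_length >= spec.genome_length:
            raise ValidationError("HGT segment must be shorter than the genome")
    if spec.repeats is not None and not 0 <= spec.repeats.cluster < spec.n_clusters:
        raise ValidationError("repeat cluster out of range")

    models = [
        random_biased_model(
            order=spec.order,
            bias_strength=spec.bias_strength,
            seed=_subseed(spec.seed, 1, c),
            model_id=f"cluster{c}",
        )
        for c in range(spec.n_clusters)
    ]
    genomes: list[Genome] = []
    truth: list[TruthRecord] = []
    feature_rng = np.random.default_rng(_subseed(spec.seed, 2))

    hgt_recipients: set[int] = set()
    if spec.hgt is not None:
        n_rec = int(round(spec.hgt.fraction * spec.genomes_per_cluster))
        hgt_recipients = set(
            feature_rng.choice(spec.genomes_per_cluster, size=n_rec, replace=False).tolist()
        )
    repeat_recipients: set[int] = set()
    if spec.repeats is not None:
        n_rep = int(round(spec.repeats.fraction * spec.genomes_per_cluster))
        repeat_recipients = set(
            feature_rng.choice(spec.genomes_per_cluster, size=n_rep, replace=False).tolist()
        )

    for c in range(spec.n_clusters):
        for g in range(spec.genomes_per_cluster):
            gid = f"c{c}_g{g}"
            member_model = jitter_model(models[c], seed=_subseed(spec.seed, 3, c, g))
            genome = generate_genome(
                member_model, spec.genome_length, seed=_subseed(spec.seed, 4, c, g), genome_id=gid
            )
            genome.label = f"cluster{c}"
            features: list[TruthRecord] = []

            if spec.hgt is not None and c == spec.hgt.recipient_cluster and g in hgt_recipients:
                seg_len = spec.hgt.segment_length
                pos_rng = np.random.default_rng(_subseed(spec.seed, 5, c, g))
                start = int(pos_rng.integers(0, spec.genome_length - seg_len + 1))
                donor_model = jitter_model(
                    models[spec.hgt.donor_cluster], seed=_subseed(spec.seed, 6, c, g)
                )
                segment = _sample_sequence(
                    donor_model, seg_len, np.random.default_rng(_subseed(spec.seed, 7, c, g))
                )
                genome.sequence = (
                    genome.sequence[:start] + segment + genome.sequence[start + seg_len :]
                )
                features.append(TruthRecord(gid, c, "hgt", start, start + seg_len))

            if spec.repeats is not None and c == spec.repeats.cluster and g in repeat_recipients:
                block = spec.repeats.unit.upper() * spec.repeats.copies
                pos_rng = np.random.default_rng(_subseed(spec.seed, 8, c, g))
                start = int(pos_rng.integers(0, len(genome.sequence) + 1))
                genome.sequence = genome.sequence[:start] + block + genome.sequence[start:]
                features.append(TruthRecord(gid, c, "repeat", start, start + len(block)))

            genomes.append(genome)
            if features:
                truth.extend(features)
            else:
                truth.append(TruthRecord(genome_id=gid, cluster=c, feature_type="none"))
    return genomes, truth


def write_truth(records: list[TruthRecord], path) -> None:
    """Write ground truth as TSV: genome_id, cluster, feature_type, start, end."""
    with open(path, "w") as fh:
        fh.write("genome_id\tcluster\tfeature_type\tstart\tend\n")
        for r in records:
            fh.write(f"{r.genome_id}\t{r.cluster}\t{r.feature_type}\t{r.start}\t{r.end}\n")
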