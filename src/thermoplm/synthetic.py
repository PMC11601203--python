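"""Synthetic data generators: protein families, OGT labels, fitness landscapes.

Everything the rest of the package needs for end-to-end exercise without any
downloads:

* **FamilyModel** — homologs drawn around a consensus sequence: each site
  mutates independently with a per-site rate, substitutions drawn from
  per-site preference distributions.
* **SyntheticOgtModel** — organism growth temperature as a linear function of
  amino-acid composition plus Gaussian noise, clamped to 0–100 °C.  This
  emulates the real signal (thermophile proteomes are enriched in I, V, Y, W,
  R, E, L) without claiming its precise coefficients.
* **EpistaticLandscape** — ground-truth fitness: additive single-site effects
  plus sparse pairwise epistasis with a predominantly negative sign (the
  empirical regime where deleterious interactions vastly outnumber beneficial
  ones), plus per-variant measurement noise.  The noise is seeded from the
  variant identity, so repeated queries behave like repeated assays of the
  same clone.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .scoring import Mutation, Variant
from .vocab import CANONICAL_RESIDUES, DEFAULT_VOCAB

# ------------------------------------------------------------------ families

DEFAULT_CONSENSUS = (
    "MKVLITGAGSGIGLELVKQLLAEGHEVIALDRSEEKLQALREELGDNVIPLVGDVRDEAFV"
    "KRAVEEAVAKFGRIDVLVNNAGIMPSAPLEELTEEQWDRVIDVNLKGVFLVSQAAARHMVK"
)


@dataclass(frozen=True)
class FamilyModel:
    """Homolog generator around a consensus sequence.

    ``rates`` may be a scalar (same substitution probability at every site)
    or a length-L vector; ``preferences`` is an optional (L, 20) table of
    per-site substitution distributions (default: uniform over the 19
    non-consensus residues).
    """

    consensus: str = DEFAULT_CONSENSUS
    rates: float | np.ndarray = 0.25
    preferences: np.ndarray | None = None
    seed: int = 0

    def site_rates(self) -> np.ndarray:
        L = len(self.consensus)
        r = np.broadcast_to(np.asarray(self.rates, dtype=float), (L,))
        if ((r < 0) | (r > 1)).any():
            raise ValueError("substitution rates must lie in [0, 1]")
        return r

    def site_preferences(self) -> np.ndarray:
        L = len(self.consensus)
        if self.preferences is not None:
            p = np.asarray(self.preferences, dtype=float)
            if p.shape != (L, 20) or not np.allclose(p.sum(1), 1.0):
                raise ValueError("preferences must be (L, 20) simplices")
            return p
        p = np.full((L, 20), 1.0 / 19.0)
        idx = [DEFAULT_VOCAB.index(aa) for aa in self.consensus]
        p[np.arange(L), idx] = 0.0
        return p


def generate_family(model: FamilyModel, n: int,
                    rng: np.random.Generator | None = None) -> list[str]:
    """Draw ``n`` homologous sequences (consensus length preserved)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    rates = model.site_rates()
    prefs = model.site_preferences()
    L = len(model.consensus)
    out = []
    for _ in range(n):
        chars = list(model.consensus)
        hits = np.nonzero(rng.random(L) < rates)[0]
        for i in hits:
            chars[i] = CANONICAL_RESIDUES[rng.choice(20, p=prefs[i])]
        out.append("".join(chars))
    return out


# ------------------------------------------------------------------ OGT model

#: Default composition weights (°C per unit residue frequency).  Positive for
#: the thermophily-associated residues, negative for polar/flexible ones.
DEFAULT_OGT_WEIGHTS = {
    "I": 90.0, "V": 70.0, "Y": 60.0, "W": 50.0, "R": 60.0, "E": 80.0,
    "L": 50.0, "K": 30.0, "G": -20.0, "Q": -40.0, "N": -50.0, "S": -40.0,
    "T": -30.0, "D": -20.0, "A": 0.0, "C": 0.0, "F": 20.0, "H": 0.0,
    "M": 10.0, "P": -10.0,
}


@dataclass(frozen=True)
class SyntheticOgtModel:
    """OGT = base + weights · composition + Gaussian noise, clamped [0,100]."""

    base: float = 30.0
    weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OGT_WEIGHTS))
    noise_sd: float = 3.0
    clamp: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.clamp[0] > self.clamp[1]:
            raise ValueError("clamp bounds out of order")

    def weight_vector(self) -> np.ndarray:
        return np.array([self.weights.get(aa, 0.0)
                         for aa in CANONICAL_RESIDUES])


def composition(seq: str) -> np.ndarray:
    """Length-20 residue-frequency vector (vocabulary order)."""
    counts = np.zeros(20)
    for ch in seq:
        counts[DEFAULT_VOCAB.index(ch)] += 1
    return counts / len(seq)


def assign_ogt(seq: str, model: SyntheticOgtModel,
               rng: np.random.Generator) -> float:
    """Sample one noisy OGT label (°C) for a sequence."""
    mean = model.base + float(model.weight_vector() @ composition(seq))
    noise = rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 else 0.0
    return float(np.clip(mean + noise, *model.clamp))


def make_ogt_corpus(family: FamilyModel, ogt_model: SyntheticOgtModel,
                    n: int, seed: int) -> list[tuple[str, str, float]]:
    """(id, sequence, OGT) records for pretraining."""
    rng = np.random.default_rng(seed)
    seqs = generate_family(family, n, rng)
    return [(f"syn{i:05d}", s, assign_ogt(s, ogt_model, rng))
            for i, s in enumerate(seqs)]


# ----------------------------------------------------------------- landscape

def _variant_seed(base_seed: int, variant: Variant) -> int:
    return (base_seed * 2654435761 + zlib.crc32(str(variant).encode())) % (2**31)


@dataclass
class EpistaticLandscape:
    """Additive + pairwise ground-truth fitness over a wild type.

    ``additive`` maps "wtPOSmut" strings to single-site effects (the
    wild-type residue's own effect is identically zero); ``epistasis`` maps
    unordered pairs of those strings to interaction terms.  A variant's mean
    fitness is the sum of its additive effects plus the epistasis of every
    declared pair it contains.  Mutations absent from the table receive a
    deterministic pseudo-random additive effect derived from the landscape
    seed, so the oracle is total over all variants.
    """

    wild_type: str
    additive: dict[str, float]
    epistasis: dict[frozenset, float]
    noise_sd: float = 0.0
    negative_fraction: float = 0.9
    seed: int = 0

    # -- evaluation --------------------------------------------------------
    def _additive_effect(self, m: Mutation) -> float:
        key = str(m)
        if key in self.additive:
            return self.additive[key]
        if m.mut == m.wt:
            return 0.0
        rng = np.random.default_rng(
            [self.seed, m.position, DEFAULT_VOCAB.index(m.mut)])
        return float(rng.normal(0.0, 1.0))

    def mean_fitness(self, variant: Variant) -> float:
        total = sum(self._additive_effect(m) for m in variant.mutations)
        keys = [str(m) for m in variant.mutations]
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                total += self.epistasis.get(frozenset((keys[i], keys[j])), 0.0)
        return float(total)

    def fitness(self, variant: Variant, noisy: bool = True,
                tag: int = 0) -> float:
        """Assay-style measurement; noise reproducible per (variant, tag).

        Repeated queries with the same ``tag`` return the same value (one
        clone, one measurement); a different ``tag`` behaves like an
        independent assay campaign.
        """
        mu = self.mean_fitness(variant)
        if not noisy or self.noise_sd == 0.0:
            return mu
        rng = np.random.default_rng([_variant_seed(self.seed, variant), tag])
        return mu + float(rng.normal(0.0, self.noise_sd))

    __call__ = fitness

    def singles(self) -> list[Mutation]:
        """The single-site mutations the landscape declares effects for."""
        out = [_parse_mutation_key(key) for key in self.additive]
        return sorted(out, key=lambda m: (m.position, m.mut))

    # -- (de)serialization ---------------------------------------------------
    def to_json(self) -> str:
        payload = dict(
            schema="epistatic-landscape/1",
            wild_type=self.wild_type,
            additive=dict(sorted(self.additive.items())),
            epistasis=[[sorted(pair), e] for pair, e in
                       sorted(self.epistasis.items(),
                              key=lambda kv: sorted(kv[0]))],
            noise_sd=self.noise_sd,
            negative_fraction=self.negative_fraction,
            seed=self.seed,
        )
        return json.dumps(payload, indent=1, sort_keys=False)

    @classmethod
    def from_json(cls, text: str) -> "EpistaticLandscape":
        d = json.loads(text)
        if d.get("schema") != "epistatic-landscape/1":
            raise ValueError("unrecognized landscape schema")
        return cls(wild_type=d["wild_type"], additive=d["additive"],
                   epistasis={frozenset(pair): e for pair, e in d["epistasis"]},
                   noise_sd=d["noise_sd"],
                   negative_fraction=d["negative_fraction"], seed=d["seed"])


def _parse_mutation_key(key: str) -> Mutation:
    return Mutation(int(key[1:-1]), key[0], key[-1])


def landscape_fitness(landscape: EpistaticLandscape, variant: Variant,
                      noisy: bool = True) -> float:
    """Functional alias for :meth:`EpistaticLandscape.fitness`."""
    return landscape.fitness(variant, noisy=noisy)


def make_landscape(wild_type: str, n_singles: int = 15, seed: int = 0,
                   additive_sd: float = 1.0, pair_fraction: float = 0.4,
                   epistasis_sd: float = 0.3, negative_fraction: float = 0.9,
                   noise_sd: float = 0.05) -> EpistaticLandscape:
    """Sample a landscape over ``n_singles`` random single-site mutations.

    Pairwise terms are drawn for a ``pair_fraction`` subset of mutation
    pairs; a ``negative_fraction`` share of them has its sign forced
    negative, echoing the strong empirical excess of negative epistasis.
    """
    rng = np.random.default_rng(seed)
    L = len(wild_type)
    positions = rng.choice(L, size=min(n_singles, L), replace=False) + 1
    singles = []
    for pos in sorted(positions.tolist()):
        wt = wild_type[pos - 1]
        choices = [aa for aa in CANONICAL_RESIDUES if aa != wt]
        singles.append(Mutation(pos, wt, choices[rng.integers(0, 19)]))
    additive = {str(m): float(rng.normal(0.0, additive_sd)) for m in singles}
    keys = [str(m) for m in singles]
    all_pairs = [(i, j) for i in range(len(keys))
                 for j in range(i + 1, len(keys))]
    n_pairs = int(round(pair_fraction * len(all_pairs)))
    pair_idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    # realize the declared negative fraction exactly: the first
    # round(frac * n) interacting pairs (in shuffled order) get a negative sign
    n_neg = int(round(negative_fraction * n_pairs))
    epistasis: dict[frozenset, float] = {}
    for rank, pi in enumerate(pair_idx):
        i, j = all_pairs[pi]
        mag = abs(rng.normal(0.0, epistasis_sd))
        sign = -1.0 if rank < n_neg else 1.0
        epistasis[frozenset((keys[i], keys[j]))] = float(sign * mag)
    return EpistaticLandscape(wild_type, additive, epistasis,
                              noise_sd=noise_sd,
                              negative_fraction=negative_fraction, seed=seed)


def realized_negative_fraction(landscape: EpistaticLandscape) -> float:
    values = np.array(list(landscape.epistasis.values()))
    if values.size == 0:
        return float("nan")
    return float((values < 0).mean())


# ------------------------------------------------------------------- fixtures

def helix_coordinates(length: int, rise: float = 1.5, radius: float = 2.3,
                      turn_deg: float = 100.0) -> dict[int, np.ndarray]:
    """One 3-D point per residue along an idealized alpha-helical curve."""
    theta = np.deg2rad(turn_deg) * np.arange(length)
    pts = np.stack([radius * np.cos(theta), radius * np.sin(theta),
                    rise * np.arange(length)], axis=1)
    return {i + 1: pts[i:i + 1] for i in range(length)}


def make_fixtures(out_dir, seed: int = 0, n_family: int = 60,
                  n_corpus: int = 120) -> dict[str, Path]:
    """Write a self-consistent fixture set; byte-stable for a given seed.

    Produces a FASTA homolog family, an OGT-labeled corpus CSV, an assay CSV
    of labeled single mutants, a per-residue coordinate CSV and a landscape
    JSON, all around the same wild type.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    wt = DEFAULT_CONSENSUS
    paths = {}

    family = generate_family(FamilyModel(consensus=wt), n_family, rng)
    paths["family"] = out / "family.fasta"
    with open(paths["family"], "w") as fh:
        fh.write(f">wild_type\n{wt}\n")
        for i, s in enumerate(family):
            fh.write(f">homolog{i:04d}\n{s}\n")

    ogt_model = SyntheticOgtModel()
    corpus = make_ogt_corpus(FamilyModel(consensus=wt, seed=seed + 1),
                             ogt_model, n_corpus, seed + 1)
    paths["corpus"] = out / "ogt_corpus.csv"
    with open(paths["corpus"], "w") as fh:
        fh.write("id,sequence,ogt\n")
        for rid, s, t in corpus:
            fh.write(f"{rid},{s},{t!r}\n")

    landscape = make_landscape(wt, n_singles=15, seed=seed)
    paths["landscape"] = out / "landscape.json"
    paths["landscape"].write_text(landscape.to_json() + "\n")

    paths["assay"] = out / "assay_singles.csv"
    with open(paths["assay"], "w") as fh:
        fh.write("mutant,score\n")
        for m in landscape.singles():
            f = landscape.fitness(Variant((m,)))
            fh.write(f"{m},{f!r}\n")

    coords = helix_coordinates(len(wt))
    paths["coords"] = out / "coords.csv"
    with open(paths["coords"], "w") as fh:
        fh.write("position,x,y,z\n")
        for pos in range(1, len(wt) + 1):
            for x, y, z in coords[pos]:
                fh.write(f"{pos},{float(x)!r},{float(y)!r},{float(z)!r}\n")
    return paths
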