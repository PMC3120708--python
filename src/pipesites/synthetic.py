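"""Self-contained synthetic fixtures with known ground truth.

Emulates the premise behind landscape-based site prediction: short
polypeptide motifs that re-occur across proteins mediate many interactions.
The generator plants a motif pair into two groups of carrier proteins,
wires carrier-group pairs into an interaction database (plus background
noise pairs), and holds one carrier pair out as the query whose true site
rectangle is known from the insertion coordinates.

Planted motifs are longer than the matching window by default so the true
site appears as a peak with a supporting plateau of co-occurring windows —
the shape real landscapes exhibit — rather than a single-cell spike, which
the spurious-peak filter rejects by design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import Interval, InteractionDB, LabSitePair, Protein

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MotifPairSpec:
    """One planted motif pair and its carrier configuration.

    ``motif_a``/``motif_b`` of None means: draw a random motif of length
    ``SynthParams.motif_length`` from the seeded generator.
    """

    motif_a: str | None = None
    motif_b: str | None = None
    n_carriers_a: int = 6
    n_carriers_b: int = 6
    density: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("carrier interaction density must be in [0,1]")
        if self.n_carriers_a < 1 or self.n_carriers_b < 1:
            raise ValueError("carrier counts must be >= 1")


@dataclass(frozen=True)
class SynthParams:
    """Generator configuration; the seed is mandatory."""

    seed: int
    n_proteins: int = 30
    length_range: tuple[int, int] = (80, 200)
    motif_pairs: tuple[MotifPairSpec, ...] = (MotifPairSpec(),)
    motif_length: int = 14
    window_length: int = 10
    background_rate: float = 0.02
    annotate_motifs: bool = True

    def __post_init__(self) -> None:
        if self.n_proteins < 2:
            raise ValueError("need at least 2 proteins")
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background_rate must be in [0,1]")
        total_carriers = sum(
            m.n_carriers_a + m.n_carriers_b for m in self.motif_pairs
        )
        if total_carriers > self.n_proteins:
            raise ValueError(
                f"carrier counts ({total_carriers}) exceed n_proteins "
                f"({self.n_proteins})"
            )
        for m in self.motif_pairs:
            for motif in (m.motif_a, m.motif_b):
                if motif is not None and len(motif) < self.window_length:
                    raise ValueError(
                        f"motif {motif!r} shorter than window length "
                        f"{self.window_length}"
                    )
        if self.motif_length < self.window_length:
            raise ValueError("motif_length must be >= window_length")
        if self.length_range[0] < self.motif_length:
            raise ValueError("minimum protein length must fit the motif")


@dataclass
class PlantedPair:
    """Ground truth for one held-out query pair."""

    id_a: str
    id_b: str
    range_a: Interval            # motif insertion coordinates on A
    range_b: Interval
    carriers_a: list[str]
    carriers_b: list[str]
    expected_min_height: int     # oriented carrier pairs left in the DB


@dataclass
class GroundTruth:
    """Planted truth for every held-out query pair, keyed by (idA, idB)."""

    pairs: dict[tuple[str, str], PlantedPair] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            f"{a}\t{b}": {
                "range_a": list(p.range_a),
                "range_b": list(p.range_b),
                "carriers_a": p.carriers_a,
                "carriers_b": p.carriers_b,
                "expected_min_height": p.expected_min_height,
            }
            for (a, b), p in sorted(self.pairs.items())
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class SyntheticDataset:
    """In-memory fixture set; ``write`` serializes to plain-text files."""

    proteome: dict[str, Protein]
    db: InteractionDB
    lab_sites: list[LabSitePair]
    annotations: list[tuple[str, str, str, int, int]]
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "proteome.fasta",
            "pairs": out / "pairs.tsv",
            "lab_sites": out / "lab_sites.tsv",
            "annotations": out / "annotations.tsv",
            "truth": out / "truth.json",
        }
        with open(paths["fasta"], "w", encoding="utf-8") as fh:
            for pid in sorted(self.proteome):
                fh.write(f">{pid}\n{self.proteome[pid].sequence}\n")
        with open(paths["pairs"], "w", encoding="utf-8") as fh:
            for a, b in sorted(self.db.pairs):
                fh.write(f"{a}\t{b}\n")
        with open(paths["lab_sites"], "w", encoding="utf-8") as fh:
            for s in self.lab_sites:
                fh.write(
                    f"{s.id_a}\t{s.id_b}\t{s.range_a[0]}\t{s.range_a[1]}"
                    f"\t{s.range_b[0]}\t{s.range_b[1]}\n"
                )
        with open(paths["annotations"], "w", encoding="utf-8") as fh:
            for row in self.annotations:
                fh.write("\t".join(str(x) for x in row) + "\n")
        paths["truth"].write_text(self.truth.to_json(), encoding="utf-8")
        return paths


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA20), size=length))


def generate_dataset(params: SynthParams) -> SyntheticDataset:
    """Generate a proteome, interaction DB, lab-site file and ground truth.

    For each motif pair: motif_a is overwritten into ``n_carriers_a``
    distinct proteins at recorded positions (likewise motif_b); carrier
    cross pairs enter the DB at the stated density; one a-carrier/b-carrier
    pair is held out as the query, its true insertion ranges listed in the
    lab-sites table. Background pairs among non-carrier combinations are
    added at ``background_rate``. Identical seed -> byte-identical outputs.
    """
    rng = np.random.default_rng(params.seed)
    width = len(str(params.n_proteins))
    ids = [f"SYN{str(i + 1).zfill(width)}" for i in range(params.n_proteins)]
    lo, hi = params.length_range
    sequences = {
        pid: list(_random_sequence(rng, int(rng.integers(lo, hi + 1))))
        for pid in ids
    }

    free = list(ids)
    truth = GroundTruth()
    lab_sites: list[LabSitePair] = []
    annotations: list[tuple[str, str, str, int, int]] = []
    carrier_pair_sets: list[set[tuple[str, str]]] = []
    carrier_ids: set[str] = set()

    for m_idx, spec in enumerate(params.motif_pairs, start=1):
        motif_a = spec.motif_a or _random_sequence(rng, params.motif_length)
        motif_b = spec.motif_b or _random_sequence(rng, params.motif_length)
        n_take = spec.n_carriers_a + spec.n_carriers_b
        chosen = list(rng.choice(free, size=n_take, replace=False))
        carriers_a, carriers_b = chosen[: spec.n_carriers_a], chosen[spec.n_carriers_a:]
        free = [pid for pid in free if pid not in set(chosen)]
        carrier_ids.update(chosen)

        positions: dict[str, Interval] = {}
        for group, motif, tag in (
            (carriers_a, motif_a, "a"),
            (carriers_b, motif_b, "b"),
        ):
            for pid in group:
                length = len(sequences[pid])
                start = int(rng.integers(1, length - len(motif) + 2))
                sequences[pid][start - 1:start - 1 + len(motif)] = list(motif)
                positions[pid] = (start, start + len(motif) - 1)
                if params.annotate_motifs:
                    annotations.append(
                        (pid, f"SYNMOT{m_idx}", f"planted_motif_{m_idx}",
                         positions[pid][0], positions[pid][1])
                    )

        pairs = {
            (a, b)
            for a in carriers_a
            for b in carriers_b
            if rng.random() < spec.density
        }
        qa = carriers_a[int(rng.integers(len(carriers_a)))]
        qb = carriers_b[int(rng.integers(len(carriers_b)))]
        pairs.discard((qa, qb))
        carrier_pair_sets.append(pairs)
        truth.pairs[(qa, qb)] = PlantedPair(
            id_a=qa,
            id_b=qb,
            range_a=positions[qa],
            range_b=positions[qb],
            carriers_a=sorted(carriers_a),
            carriers_b=sorted(carriers_b),
            expected_min_height=len(pairs),
        )
        lab_sites.append(LabSitePair(qa, qb, positions[qa], positions[qb]))

    proteome = {pid: Protein(pid, "".join(sequences[pid])) for pid in ids}
    db = InteractionDB(proteome=proteome)
    for pairs in carrier_pair_sets:
        for a, b in sorted(pairs):
            db.add(a, b)

    # background noise pairs: any combination that is not carrier-to-carrier
    held_out = set(truth.pairs)
    for idx_a in range(len(ids)):
        for idx_b in range(idx_a + 1, len(ids)):
            a, b = ids[idx_a], ids[idx_b]
            if a in carrier_ids and b in carrier_ids:
                continue
            if rng.random() < params.background_rate:
                if (a, b) not in held_out and (b, a) not in held_out:
                    db.add(a, b)

    return SyntheticDataset(
        proteome=proteome,
        db=db,
        lab_sites=lab_sites,
        annotations=annotations,
        truth=truth,
    )


def expected_peak_cell(truth: GroundTruth, id_a: str, id_b: str) -> tuple[int, int]:
    """Window-start indices of the planted motifs on a held-out query pair.

    With exact matching and w <= motif length, the landscape cell at the
    two insertion starts receives one count per oriented carrier pair.
    """
    key = (id_a, id_b)
    if key not in truth.pairs:
        raise KeyError(f"pair ({id_a}, {id_b}) was not planted")
    planted = truth.pairs[key]
    return planted.range_a[0], planted.range_b[0]
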