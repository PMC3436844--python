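"""Synthetic protein databases with planted families and mutated queries.

The generator emulates the structure of a homology-retrieval benchmark: a
background of unrelated random proteins, a set of planted families derived
from founder proteins by independent point substitutions at controlled
rates, and query sets that are further mutated copies of the founders.
Controlled substitution rates put query/target pairs at known sequence
identity, so the feasible regime of a word filter (roughly 50-100%
identity) can be probed without any external database.  Everything is
driven by one integer seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

__all__ = ["BenchmarkSpec", "Benchmark", "random_protein", "mutate", "make_benchmark"]


@dataclass
class BenchmarkSpec:
    """Recipe for one synthetic benchmark.

    ``n_proteins`` unrelated background proteins form the database; the
    first ``n_families`` of them act as family founders.  Each family adds
    ``family_size - 1`` mutated copies of its founder to the database and
    ``query_replicates`` mutated queries per substitution rate in
    ``identity_levels`` (a rate of 0.3 plants ~70% identity).  Lengths are
    drawn log-normally with the given mean and clipped to [min, max];
    setting min == max fixes the length.
    """

    n_proteins: int = 1000
    length_min: int = 50
    length_mean: float = 330.0
    length_max: int = 2000
    n_families: int = 50
    family_size: int = 1
    identity_levels: list[float] = field(default_factory=lambda: [0.3])
    query_replicates: int = 20
    indel_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1 or self.n_families < 0 or self.family_size < 1:
            raise ValueError("counts must be positive")
        if self.n_families > self.n_proteins:
            raise ValueError("more families than database proteins")
        if not 1 <= self.length_min <= self.length_max:
            raise ValueError("bad length bounds")
        if any(not 0.0 <= r <= 1.0 for r in self.identity_levels) or not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("rates must lie in [0, 1]")


@dataclass
class Benchmark:
    """In-memory benchmark: FASTA-ready records plus truth rows."""

    db_records: list[tuple[str, str]]
    query_records: list[tuple[str, str]]
    truth: list[tuple[str, str, float]]  # (query_id, target_id, identity %)


def random_protein(length: int, rng: np.random.Generator, composition: dict[str, float] | None = None) -> str:
    """An i.i.d. random protein over the 20-letter alphabet."""
    if length < 1:
        raise ValueError("length must be >= 1")
    letters = np.array(list(ALPHABET))
    p = None
    if composition is not None:
        p = np.array([composition.get(c, 0.0) for c in ALPHABET])
        p = p / p.sum()
    return "".join(rng.choice(letters, size=length, p=p))


def mutate(seq: str, rate: float, rng: np.random.Generator, indel_rate: float = 0.0) -> str:
    """Point-substitute each position independently with probability ``rate``.

    A substituted position always receives a *different* residue, so the
    expected identity to the original is exactly ``1 - rate``.  With a
    nonzero ``indel_rate``, single-residue insertions and deletions are
    additionally applied per position (equiprobable), changing the length.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    if hit.any():
        # shift each hit residue by 1..19 places around the 20-letter wheel
        idx = np.array([ALPHABET.index(chr(c)) for c in arr[hit]])
        shift = rng.integers(1, len(ALPHABET), size=hit.sum())
        arr[hit] = np.frombuffer(
            "".join(ALPHABET[(i + s) % len(ALPHABET)] for i, s in zip(idx, shift)).encode("ascii"),
            dtype=np.uint8,
        )
    out = arr.tobytes().decode("ascii")
    if indel_rate > 0.0:
        chars = []
        for c in out:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            chars.append(c)
            if indel_rate / 2 <= r < indel_rate:
                chars.append(ALPHABET[rng.integers(0, len(ALPHABET))])
        out = "".join(chars) or out[:1]
    return out


def _identity(a: str, b: str) -> float:
    """Percent of equal positions over the shorter length (ungapped)."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    eq = sum(1 for x, y in zip(a[:n], b[:n]) if x == y)
    return 100.0 * eq / n


def _draw_length(spec: BenchmarkSpec, rng: np.random.Generator) -> int:
    if spec.length_min == spec.length_max:
        return spec.length_min
    # log-normal with the requested mean; sigma echoes real length spread
    sigma = 0.45
    mu = np.log(spec.length_mean) - sigma**2 / 2
    return int(np.clip(np.round(rng.lognormal(mu, sigma)), spec.length_min, spec.length_max))


def make_benchmark(spec: BenchmarkSpec, out_dir: str | Path | None = None) -> Benchmark:
    """Generate database, query set and truth table from a spec.

    The database holds ``n_proteins`` unrelated proteins plus the extra
    family members; each query's truth row lists every member of its family
    (founder included) with the observed ungapped identity percentage.
    With ``out_dir`` set, writes ``db.fasta``, ``query.fasta`` and
    ``truth.tsv`` (deterministic bytes for a fixed spec).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    db_records = [
        (f"D{i:05d}", random_protein(_draw_length(spec, rng), rng)) for i in range(spec.n_proteins)
    ]
    families: list[list[tuple[str, str]]] = []
    for f in range(spec.n_families):
        founder_id, founder_seq = db_records[f]
        members = [(founder_id, founder_seq)]
        for j in range(1, spec.family_size):
            rate = spec.identity_levels[j % len(spec.identity_levels)]
            mid = f"F{f:03d}_M{j}"
            members.append((mid, mutate(founder_seq, rate, rng, spec.indel_rate)))
            db_records.append(members[-1])
        families.append(members)
    query_records: list[tuple[str, str]] = []
    truth: list[tuple[str, str, float]] = []
    for f, members in enumerate(families):
        founder_seq = members[0][1]
        for rate in spec.identity_levels:
            for rep in range(spec.query_replicates):
                qid = f"Q{f:03d}_r{int(round(rate * 100)):02d}_{rep:02d}"
                qseq = mutate(founder_seq, rate, rng, spec.indel_rate)
                query_records.append((qid, qseq))
                for tid, tseq in members:
                    truth.append((qid, tid, round(_identity(qseq, tseq), 2)))
    bench = Benchmark(db_records=db_records, query_records=query_records, truth=truth)
    if out_dir is not None:
        write_benchmark(bench, out_dir)
    return bench


def write_benchmark(bench: Benchmark, out_dir: str | Path) -> tuple[Path, Path, Path]:
    """Write db.fasta, query.fasta and truth.tsv; returns the three paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = (out_dir / "db.fasta", out_dir / "query.fasta", out_dir / "truth.tsv")
    for path, records in zip(paths[:2], (bench.db_records, bench.query_records)):
        with open(path, "w") as fh:
            for name, seq in records:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
    with open(paths[2], "w") as fh:
        fh.write("#query_id\ttarget_id\tidentity\n")
        for q, t, ident in bench.truth:
            fh.write(f"{q}\t{t}\t{ident:g}\n")
    return paths
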