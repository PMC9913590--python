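"""Core containers for diploid codominant (microsatellite) genotypes.

A :class:`GenotypeTable` holds individuals x loci unordered diploid allele
calls together with population labels.  Allele labels are fragment sizes
(integers); internally calls are stored as indices into each locus' allele
registry, with ``MISSING`` (-1) marking an absent call.  Half-calls (one
allele scored, the other missing) are normalised to MISSING on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

MISSING = -1


class GenotypeError(ValueError):
    """Raised on malformed or inconsistent genotype data."""


@dataclass(frozen=True)
class Locus:
    """A codominant locus with a stable, ordered allele-label registry."""

    name: str
    alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.alleles)) != len(self.alleles):
            raise GenotypeError(f"duplicate allele labels at locus {self.name}")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def index_of(self, label: int) -> int:
        try:
            return self.alleles.index(label)
        except ValueError:
            raise GenotypeError(
                f"allele {label} not registered at locus {self.name}"
            ) from None


class GenotypeTable:
    """Individuals x loci diploid genotype calls with population labels.

    Parameters
    ----------
    ids : individual identifiers (unique not required, order preserved).
    pops : population label per individual (same length as *ids*).
    loci : list of :class:`Locus`.
    calls : int array (n_individuals, n_loci, 2) of allele *indices* into
        each locus registry; both entries ``MISSING`` for a missing call.
        Pairs are unordered and stored sorted.
    """

    def __init__(
        self,
        ids: Sequence[str],
        pops: Sequence[str],
        loci: Sequence[Locus],
        calls: np.ndarray,
    ) -> None:
        ids = list(ids)
        pops = list(pops)
        loci = list(loci)
        calls = np.asarray(calls, dtype=np.int32)
        if len(ids) != len(pops):
            raise GenotypeError("ids and pops length mismatch")
        if calls.shape != (len(ids), len(loci), 2):
            raise GenotypeError(
                f"calls shape {calls.shape} does not match "
                f"({len(ids)}, {len(loci)}, 2)"
            )
        if len({l.name for l in loci}) != len(loci):
            raise GenotypeError("duplicate locus names")
        if len(ids) and not all(pops):
            raise GenotypeError("empty population label")
        # normalise: half-calls -> MISSING; sort pairs
        calls = calls.copy()
        half = (calls == MISSING).any(axis=2) & ~(calls == MISSING).all(axis=2)
        calls[half] = MISSING
        calls = np.sort(calls, axis=2)
        miss = (calls == MISSING).any(axis=2)
        calls[miss] = MISSING
        for j, locus in enumerate(loci):
            col = calls[:, j, :]
            bad = col[(col != MISSING) & ((col < 0) | (col >= locus.n_alleles))]
            if bad.size:
                raise GenotypeError(
                    f"allele index out of registry range at locus {locus.name}"
                )
        self.ids = ids
        self.pops = pops
        self.loci = loci
        self.calls = calls

    # -- basic introspection ------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.pops:
            seen.setdefault(p)
        return list(seen)

    def pop_mask(self, pop: str) -> np.ndarray:
        mask = np.array([p == pop for p in self.pops])
        if not mask.any():
            raise GenotypeError(f"unknown population {pop!r}")
        return mask

    def locus_index(self, name: str) -> int:
        for j, locus in enumerate(self.loci):
            if locus.name == name:
                return j
        raise GenotypeError(f"unknown locus {name!r}")

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): True where the call is missing."""
        return (self.calls == MISSING).all(axis=2)

    # -- derived views ------------------------------------------------------

    def subset(
        self,
        individuals: Sequence[int] | np.ndarray | None = None,
        loci: Sequence[int] | None = None,
    ) -> "GenotypeTable":
        idx = (
            np.arange(self.n_individuals)
            if individuals is None
            else np.asarray(individuals)
        )
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        ljx = list(range(self.n_loci)) if loci is None else list(loci)
        return GenotypeTable(
            [self.ids[i] for i in idx],
            [self.pops[i] for i in idx],
            [self.loci[j] for j in ljx],
            self.calls[np.ix_(idx, ljx)],
        )

    def restrict_pops(self, pops: Sequence[str]) -> "GenotypeTable":
        keep = np.array([p in set(pops) for p in self.pops])
        return self.subset(individuals=keep)

    def allele_count_matrix(self) -> np.ndarray:
        """Individuals x (sum of allele counts) per-allele dosage coding.

        Missing calls contribute the population-free column mean dosage
        (2 * overall frequency), the usual coding for PCA/DAPC.
        """
        cols = []
        for j, locus in enumerate(self.loci):
            dose = np.zeros((self.n_individuals, locus.n_alleles))
            pair = self.calls[:, j, :]
            ok = pair[:, 0] != MISSING
            for c in range(2):
                np.add.at(dose, (np.flatnonzero(ok), pair[ok, c]), 1.0)
            if ok.any():
                mean = dose[ok].mean(axis=0)
            else:
                mean = np.zeros(locus.n_alleles)
            dose[~ok] = mean
            cols.append(dose)
        return np.hstack(cols) if cols else np.zeros((self.n_individuals, 0))

    def relabel_pops(self, mapping: Mapping[str, str]) -> "GenotypeTable":
        return GenotypeTable(
            self.ids,
            [mapping.get(p, p) for p in self.pops],
            self.loci,
            self.calls,
        )

    # -- label-level access (round-trip fidelity) ---------------------------

    def call_labels(self, i: int, j: int) -> tuple[int, int] | None:
        a, b = self.calls[i, j]
        if a == MISSING:
            return None
        locus = self.loci[j]
        return (locus.alleles[a], locus.alleles[b])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        if self.ids != other.ids or self.pops != other.pops:
            return False
        if [l.name for l in self.loci] != [l.name for l in other.loci]:
            return False
        for i in range(self.n_individuals):
            for j in range(self.n_loci):
                if self.call_labels(i, j) != other.call_labels(i, j):
                    return False
        return True

    def __repr__(self) -> str:
        return (
            f"<GenotypeTable {self.n_individuals} individuals x "
            f"{self.n_loci} loci, pops={self.populations}>"
        )


def concat_tables(tables: Sequence[GenotypeTable]) -> GenotypeTable:
    """Stack tables sharing the same locus panel (names and registries)."""
    if not tables:
        raise GenotypeError("nothing to concatenate")
    first = tables[0]
    names = [l.name for l in first.loci]
    for t in tables[1:]:
        if [l.name for l in t.loci] != names:
            raise GenotypeError("locus panels differ")
    # merge registries locus-wise
    merged: list[Locus] = []
    for j, name in enumerate(names):
        labels: dict[int, None] = {}
        for t in tables:
            for a in t.loci[j].alleles:
                labels.setdefault(a)
        merged.append(Locus(name, tuple(sorted(labels))))
    ids: list[str] = []
    pops: list[str] = []
    blocks = []
    for t in tables:
        ids.extend(t.ids)
        pops.extend(t.pops)
        remap = np.empty((t.n_loci,), dtype=object)
        block = np.full((t.n_individuals, t.n_loci, 2), MISSING, dtype=np.int32)
        for j in range(t.n_loci):
            lut = np.array(
                [merged[j].alleles.index(a) for a in t.loci[j].alleles],
                dtype=np.int32,
            )
            pair = t.calls[:, j, :]
            ok = pair[:, 0] != MISSING
            block[ok, j, :] = lut[pair[ok]]
        blocks.append(block)
    return GenotypeTable(ids, pops, merged, np.concatenate(blocks, axis=0))


class AlleleFreqs:
    """Per-population, per-locus allele frequencies with gene-copy counts.

    ``freqs[pop][j]`` is a vector over the locus-*j* registry summing to 1
    where any data exist; ``counts[pop][j]`` is 2 x (non-missing N).  A
    (pop, locus) cell with no data is flagged undefined (zero count, NaN
    frequencies), never silently NaN-propagating into estimators that check
    :meth:`defined`.
    """

    def __init__(
        self,
        loci: Sequence[Locus],
        freqs: Mapping[str, list[np.ndarray]],
        counts: Mapping[str, np.ndarray],
    ) -> None:
        self.loci = list(loci)
        self.freqs = {p: [np.asarray(v, float) for v in vs] for p, vs in freqs.items()}
        self.counts = {p: np.asarray(c, int) for p, c in counts.items()}
        for p, vs in self.freqs.items():
            for j, v in enumerate(vs):
                n = self.counts[p][j]
                if n > 0 and abs(v.sum() - 1.0) > 1e-12:
                    raise GenotypeError(
                        f"frequencies at ({p}, {self.loci[j].name}) do not sum to 1"
                    )

    @property
    def populations(self) -> list[str]:
        return list(self.freqs)

    def defined(self, pop: str, j: int) -> bool:
        return int(self.counts[pop][j]) > 0

    def pool(self, pop: str) -> list[np.ndarray]:
        """Per-locus frequency vectors of one population (a gamete pool)."""
        return self.freqs[pop]


def allele_freqs(table: GenotypeTable) -> AlleleFreqs:
    """Observed allele frequencies per (population, locus).

    Missing calls are excluded; gene-copy counts are 2 x non-missing N.
    """
    if table.n_individuals == 0 or table.n_loci == 0:
        raise GenotypeError("empty table")
    freqs: dict[str, list[np.ndarray]] = {}
    counts: dict[str, np.ndarray] = {}
    for pop in table.populations:
        mask = table.pop_mask(pop)
        vs: list[np.ndarray] = []
        cs = np.zeros(table.n_loci, dtype=int)
        for j, locus in enumerate(table.loci):
            pair = table.calls[mask, j, :]
            ok = pair[:, 0] != MISSING
            copies = pair[ok].ravel()
            cs[j] = copies.size
            if copies.size:
                v = np.bincount(copies, minlength=locus.n_alleles).astype(float)
                vs.append(v / v.sum())
            else:
                vs.append(np.full(locus.n_alleles, np.nan))
        freqs[pop] = vs
        counts[pop] = cs
    return AlleleFreqs(table.loci, freqs, counts)


@dataclass
class FilterReport:
    """Loci removed by :func:`filter_loci` and the reason for each."""

    removed: list[tuple[str, str]] = field(default_factory=list)

    @property
    def removed_names(self) -> list[str]:
        return [name for name, _ in self.removed]


def filter_loci(
    table: GenotypeTable, max_missing: float = 0.12
) -> tuple[GenotypeTable, FilterReport]:
    """Drop monomorphic loci and loci with excess missing data.

    A locus is removed when it is monomorphic across all populations taken
    together, or when its missing-call fraction exceeds *max_missing* in any
    single population.
    """
    report = FilterReport()
    keep: list[int] = []
    miss = table.missing_mask()
    for j, locus in enumerate(table.loci):
        pair = table.calls[:, j, :]
        observed = np.unique(pair[pair != MISSING])
        if observed.size <= 1:
            report.removed.append((locus.name, "monomorphic"))
            continue
        over = None
        for pop in table.populations:
            mask = table.pop_mask(pop)
            frac = miss[mask, j].mean()
            if frac > max_missing:
                over = (pop, frac)
                break
        if over is not None:
            report.removed.append(
                (locus.name, f"missing {over[1]:.2f} > {max_missing:.2f} in {over[0]}")
            )
            continue
        keep.append(j)
    if not keep:
        raise GenotypeError("all loci removed by filtering")
    return table.subset(loci=keep), report
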