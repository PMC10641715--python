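"""Population-genetic statistics for the wild-species sub-analysis.

Implements the classical descriptive quantities used to ask whether
R-genes that are silent in the crop but expressed in wild relatives remain
under purifying selection:

* nucleotide diversity pi — average pairwise proportion of differing
  sites within a sample (no finite-sample n/(n-1) correction; the
  convention is recorded in the output);
* between-group divergence K — mean pairwise difference proportion with
  optional Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3);
* Nei-Gojobori synonymous / nonsynonymous rates — unweighted-pathway
  counting: synonymous site fractions per codon position, differences
  partitioned by averaging over all shortest substitution pathways,
  pathways through stop codons excluded;
* pi_a / pi_s — within-species nonsynonymous vs synonymous diversity.

Ratios pi_a/pi_s << 1 (and Ka/Ks << 1) indicate purifying selection.
Sites with a gap or N in either member of a pair are skipped; codons with
a gap or N in either sequence are skipped entirely in coding mode.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "AlignedSequenceSet",
    "read_alignment",
    "nucleotide_diversity",
    "divergence",
    "jukes_cantor",
    "NeiGojoboriResult",
    "nei_gojobori",
    "pia_pis",
]

_VALID = set("ACGT-N")
_BASES = "ACGT"

_CODON_TABLE = {c: aa for c, aa in standard_dna_table.forward_table.items()}
_STOPS = set(standard_dna_table.stop_codons)


def _translate(codon: str) -> str | None:
    """Amino acid, or None for a stop codon."""
    return None if codon in _STOPS else _CODON_TABLE[codon]


@dataclass
class AlignedSequenceSet:
    """Equal-length aligned sequences over {A, C, G, T, -, N}."""

    ids: list[str]
    seqs: list[str]
    species: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and sequences differ in count")
        self.seqs = [s.upper().replace("U", "T") for s in self.seqs]
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must all have the same length")
        for sid, s in zip(self.ids, self.seqs):
            bad = set(s) - _VALID
            if bad:
                raise ValueError(f"invalid character(s) in {sid}: {', '.join(sorted(bad))}")
        if self.species is not None and len(self.species) != len(self.ids):
            raise ValueError("species labels must match sequence count")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def by_species(self) -> dict[str, list[int]]:
        if self.species is None:
            raise ValueError("no species labels attached")
        out: dict[str, list[int]] = {}
        for i, sp in enumerate(self.species):
            out.setdefault(sp, []).append(i)
        return out


def read_alignment(path, species_map: dict[str, str] | None = None) -> AlignedSequenceSet:
    """Read an aligned FASTA; ``species_map`` maps sequence id -> species."""
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    ids = [r.id for r in records]
    species = [species_map[i] for i in ids] if species_map else None
    return AlignedSequenceSet(ids=ids, seqs=[str(r.seq) for r in records], species=species)


def _pair_p_distance(a: str, b: str) -> tuple[int, int]:
    """(differences, compared sites) skipping gap/N sites in either sequence."""
    diffs = compared = 0
    for x, y in zip(a, b):
        if x in "-N" or y in "-N":
            continue
        compared += 1
        if x != y:
            diffs += 1
    return diffs, compared


def nucleotide_diversity(alignment: AlignedSequenceSet, indices=None) -> float:
    """Average pairwise difference proportion (pi) over all sequence pairs."""
    idx = list(indices) if indices is not None else list(range(len(alignment)))
    if len(idx) < 2:
        raise ValueError("pi needs at least 2 sequences")
    props = []
    for i, j in itertools.combinations(idx, 2):
        d, n = _pair_p_distance(alignment.seqs[i], alignment.seqs[j])
        if n == 0:
            warnings.warn("sequence pair with no comparable sites skipped", RuntimeWarning)
            continue
        props.append(d / n)
    if not props:
        raise ValueError("no comparable sequence pairs")
    return float(np.mean(props))


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3); NaN for p >= 0.75."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        warnings.warn(f"JC correction undefined for p = {p:.4g} >= 0.75", RuntimeWarning)
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def divergence(
    alignment: AlignedSequenceSet, group_a, group_b, jc_correct: bool = True
) -> float:
    """Mean between-group divergence K (per site), optionally JC-corrected.

    ``group_a`` / ``group_b`` are sequence indices or ids.
    """

    def resolve(group):
        out = []
        for g in group:
            out.append(g if isinstance(g, int) else alignment.ids.index(g))
        return out

    ia, ib = resolve(group_a), resolve(group_b)
    if not ia or not ib:
        raise ValueError("both groups must be nonempty")
    props = []
    for i in ia:
        for j in ib:
            d, n = _pair_p_distance(alignment.seqs[i], alignment.seqs[j])
            if n:
                props.append(d / n)
    if not props:
        raise ValueError("no comparable between-group pairs")
    p = float(np.mean(props))
    return jukes_cantor(p) if jc_correct else p


# ---------------------------------------------------------------------------
# Nei-Gojobori counting
# ---------------------------------------------------------------------------


def _codon_sites(codon: str) -> float:
    """Synonymous site count of one codon (0..3).

    Per position, the fraction of the 3 possible single-nucleotide changes
    that preserve the amino acid; changes creating a stop codon count as
    nonsynonymous.
    """
    aa = _translate(codon)
    if aa is None:
        raise ValueError(f"stop codon {codon} has no site counts")
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _translate(mutant) == aa:
                s += 1.0 / 3.0
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) differences between two codons.

    Averaged over all orderings of the differing positions; pathways that
    pass through a stop codon are excluded (all-pathways fallback when
    every ordering is blocked).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order):
        syn = nonsyn = 0.0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            aa_cur, aa_nxt = _translate(cur), _translate(nxt)
            if aa_nxt is None and nxt != c2:
                return None  # intermediate stop: blocked pathway
            if aa_nxt is None or aa_cur is None:
                nonsyn += 1.0
            elif aa_cur == aa_nxt:
                syn += 1.0
            else:
                nonsyn += 1.0
            cur = nxt
        return syn, nonsyn

    valid = [r for r in (walk(o) for o in itertools.permutations(diff_pos)) if r is not None]
    if not valid:
        valid = []
        for order in itertools.permutations(diff_pos):
            syn = nonsyn = 0.0
            cur = c1
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if _translate(cur) is not None and _translate(cur) == _translate(nxt):
                    syn += 1.0
                else:
                    nonsyn += 1.0
                cur = nxt
            valid.append((syn, nonsyn))
    syn = float(np.mean([v[0] for v in valid]))
    nonsyn = float(np.mean([v[1] for v in valid]))
    return syn, nonsyn


@dataclass
class NeiGojoboriResult:
    pn: float
    ps: float
    dn: float
    ds: float
    n_sites: float
    s_sites: float
    nd: float
    sd: float

    @property
    def dnds(self) -> float:
        return self.dn / self.ds if self.ds and not math.isnan(self.ds) else float("nan")


def _clean_codon_pairs(a: str, b: str):
    """Yield aligned stop-free codon pairs, skipping gap/N codons.

    A terminal stop codon present in both sequences is dropped; an internal
    stop is an error.
    """
    if len(a) != len(b):
        raise ValueError("coding sequences must have equal aligned length")
    if len(a) % 3:
        raise ValueError("aligned coding length must be divisible by 3")
    n_codons = len(a) // 3
    pairs = []
    for k in range(n_codons):
        ca, cb = a[3 * k : 3 * k + 3], b[3 * k : 3 * k + 3]
        if set(ca) & set("-N") or set(cb) & set("-N"):
            continue
        stop_a, stop_b = ca in _STOPS, cb in _STOPS
        if stop_a or stop_b:
            if k == n_codons - 1:
                continue  # terminal stop: not counted
            raise ValueError(f"internal stop codon at codon {k + 1}")
        pairs.append((ca, cb))
    return pairs


def nei_gojobori(codon_seq_a: str, codon_seq_b: str, jc_correct: bool = True) -> NeiGojoboriResult:
    """Nei-Gojobori (unweighted pathway) synonymous/nonsynonymous rates.

    Site counts are averaged over the two sequences; differences are
    partitioned by averaging over all shortest substitution pathways,
    excluding pathways through stop codons.  ``pn = Nd / n_sites`` and
    ``ps = Sd / s_sites``; ``dn``/``ds`` apply the Jukes-Cantor correction
    per class when requested (and equal ``pn``/``ps`` otherwise).
    """
    a = codon_seq_a.upper().replace("U", "T")
    b = codon_seq_b.upper().replace("U", "T")
    pairs = _clean_codon_pairs(a, b)
    if not pairs:
        raise ValueError("no comparable codons")
    s_sites = n_sites = sd = nd = 0.0
    for ca, cb in pairs:
        s_a, s_b = _codon_sites(ca), _codon_sites(cb)
        s_sites += (s_a + s_b) / 2.0
        n_sites += 3.0 - (s_a + s_b) / 2.0
        syn, nonsyn = _pathway_counts(ca, cb)
        sd += syn
        nd += nonsyn
    pn = nd / n_sites if n_sites else float("nan")
    ps = sd / s_sites if s_sites else float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dn = jukes_cantor(pn) if jc_correct and not math.isnan(pn) else pn
        ds = jukes_cantor(ps) if jc_correct and not math.isnan(ps) else ps
    return NeiGojoboriResult(
        pn=pn, ps=ps, dn=dn, ds=ds, n_sites=n_sites, s_sites=s_sites, nd=nd, sd=sd
    )


def pia_pis(alignment: AlignedSequenceSet, species_labels=None) -> tuple[float, float, float]:
    """Within-species nonsynonymous (pi_a) and synonymous (pi_s) diversity.

    Averages uncorrected pairwise pN and pS over all within-species pairs
    (pooled across species).  Returns ``(pi_a, pi_s, ratio)``; the ratio is
    NaN (missing) when pi_s = 0.
    """
    if species_labels is not None:
        alignment = AlignedSequenceSet(
            ids=alignment.ids, seqs=alignment.seqs, species=list(species_labels)
        )
    groups = (
        alignment.by_species()
        if alignment.species is not None
        else {"all": list(range(len(alignment)))}
    )
    pas, pss = [], []
    for members in groups.values():
        if len(members) < 2:
            continue
        for i, j in itertools.combinations(members, 2):
            res = nei_gojobori(alignment.seqs[i], alignment.seqs[j], jc_correct=False)
            pas.append(res.pn)
            pss.append(res.ps)
    if not pas:
        raise ValueError("need at least one species with >= 2 sequences")
    pi_a = float(np.mean(pas))
    pi_s = float(np.mean(pss))
    ratio = pi_a / pi_s if pi_s > 0 else float("nan")
    return pi_a, pi_s, ratio
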