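"""miR482/2118-style target prediction on coding sequences.

Plant miRNAs of the miR482 superfamily silence NBS-LRR transcripts through
near-perfect reverse-complementary pairing to the NBS-coding region.  The
scorer below implements an expectation-style penalty: the miRNA (5'->3')
is aligned against the reverse complement of a candidate mRNA site and
accumulates penalties per position — 1.0 for a mismatch, 0.5 for a G:U
wobble pair, 2.0 for a gap (at most one gap per site) — with penalties in
the seed region (miRNA positions 2-13, 1-based) multiplied by 1.5.  A
perfect reverse-complement site scores 0.  Predicted targets are the
(miRNA, CDS) pairs whose best site scores at or below a cutoff
(default 3.0); higher expectations mean less likely interactions.

The scheme is an explicit, versioned approximation of the public
psRNATarget-style scoring family; its parameters live in
:class:`ScoringScheme` so alternative weightings can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ScoringScheme",
    "SiteAlignment",
    "score_site",
    "best_site",
    "predict_targets",
    "ContingencyResult",
    "chisq_2x2",
]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class ScoringScheme:
    """Penalty weights for miRNA:target alignment (version mir482_v1)."""

    mismatch: float = 1.0
    wobble: float = 0.5
    gap: float = 2.0
    seed_start: int = 2     # 1-based miRNA position, inclusive
    seed_end: int = 13      # inclusive
    seed_multiplier: float = 1.5
    max_gaps: int = 1
    name: str = "mir482_v1"

    def position_weight(self, pos_1based: int) -> float:
        return self.seed_multiplier if self.seed_start <= pos_1based <= self.seed_end else 1.0


DEFAULT_SCHEME = ScoringScheme()


def _normalize_rna(seq: str, what: str) -> str:
    s = str(seq).upper().replace("T", "U")
    if not s:
        raise ValueError(f"empty {what} sequence")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"invalid base(s) in {what}: {', '.join(sorted(bad))}")
    return s


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _pair_penalty(m: str, rc: str, scheme: ScoringScheme) -> float:
    """Penalty for pairing miRNA base ``m`` against revcomp-site base ``rc``.

    Equality means a Watson-Crick pair.  A G:U wobble between miRNA base m
    and mRNA base t corresponds to (m, rc) in {(G, A), (U, C)} because
    rc is the complement of t.
    """
    if m == rc:
        return 0.0
    if (m, rc) in (("G", "A"), ("U", "C")):
        return scheme.wobble
    return scheme.mismatch


def score_site(mirna_seq: str, site_seq: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Expectation-style penalty of a single candidate site.

    ``site_seq`` is the mRNA site read 5'->3'; its length may differ from
    the miRNA length by at most ``scheme.max_gaps`` (a single bulge on
    either strand).  Returns the minimum penalty over the allowed
    alignments.
    """
    m = _normalize_rna(mirna_seq, "miRNA")
    site = _normalize_rna(site_seq, "site")
    rc = _revcomp(site)
    lm, ls = len(m), len(rc)
    if abs(lm - ls) > scheme.max_gaps:
        raise ValueError(
            f"site length {ls} incompatible with miRNA length {lm} "
            f"(at most {scheme.max_gaps} gap)"
        )

    def w(i: int) -> float:  # weight for 0-based miRNA index
        return scheme.position_weight(i + 1)

    if lm == ls:
        return sum(_pair_penalty(m[i], rc[i], scheme) * w(i) for i in range(lm))

    best = float("inf")
    if ls == lm + 1:
        # one unpaired (bulged) base in the target; skip rc position j
        for j in range(ls):
            pen = scheme.gap * w(min(j, lm - 1))
            for i in range(lm):
                pen += _pair_penalty(m[i], rc[i if i < j else i + 1], scheme) * w(i)
            best = min(best, pen)
    else:
        # one unpaired miRNA base; skip miRNA position j
        for j in range(lm):
            pen = scheme.gap * w(j)
            for i in range(lm):
                if i == j:
                    continue
                pen += _pair_penalty(m[i], rc[i if i < j else i - 1], scheme) * w(i)
            best = min(best, pen)
    return best


@dataclass
class SiteAlignment:
    """Best-scoring site of one miRNA on one transcript."""

    mirna_id: str
    gene_id: str
    expectation: float
    start: int   # 0-based half-open on the transcript
    end: int
    site: str    # the mRNA site, 5'->3'


def best_site(mirna_seq: str, cds_seq: str, scheme: ScoringScheme = DEFAULT_SCHEME):
    """Minimum-expectation site of ``mirna_seq`` on ``cds_seq``.

    Scans every window of miRNA length and, when ``scheme.max_gaps`` allows,
    of length +/- 1.  Returns ``(score, start, end, site)``.
    """
    m = _normalize_rna(mirna_seq, "miRNA")
    cds = _normalize_rna(cds_seq, "CDS")
    lengths = {len(m)}
    if scheme.max_gaps >= 1:
        lengths |= {len(m) - 1, len(m) + 1}
    best = (float("inf"), -1, -1, "")
    for wlen in sorted(lengths):
        if wlen < 1 or wlen > len(cds):
            continue
        for start in range(len(cds) - wlen + 1):
            site = cds[start : start + wlen]
            s = score_site(m, site, scheme)
            if s < best[0]:
                best = (s, start, start + wlen, site)
    return best


def predict_targets(
    mirna_fasta,
    cds_fasta,
    max_expectation: float = 3.0,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> pd.DataFrame:
    """Scan every (miRNA, CDS) pair and report likely target sites.

    Inputs are FASTA paths (or handles).  For each pair the best (minimum
    expectation) site is found; rows with expectation <= ``max_expectation``
    are returned.  A gene is a predicted family target if any miRNA hits
    it — use ``result.gene_id.unique()``.
    """
    mirnas = list(SeqIO.parse(mirna_fasta, "fasta"))
    cdss = list(SeqIO.parse(cds_fasta, "fasta"))
    if not mirnas:
        raise ValueError("miRNA FASTA contains no sequences")
    if not cdss:
        raise ValueError("CDS FASTA contains no sequences")
    rows = []
    for mir in mirnas:
        for cds in cdss:
            score, start, end, site = best_site(str(mir.seq), str(cds.seq), scheme)
            if score <= max_expectation:
                rows.append((mir.id, cds.id, float(score), start, end, site))
    return pd.DataFrame(
        rows, columns=["mirna_id", "gene_id", "expectation", "start", "end", "site"]
    )


@dataclass
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    dof: int
    p_value: float
    yates: bool


def chisq_2x2(table, yates: bool = False) -> ContingencyResult:
    """Pearson chi-square test of independence for a 2x2 table.

    Uncorrected by default (``yates=True`` enables the continuity
    correction).  All margins must be positive.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("all row and column margins must be positive")
    from scipy.stats import chi2_contingency

    chi2, p, dof, expected = chi2_contingency(obs, correction=yates)
    return ContingencyResult(
        observed=obs.astype(int),
        expected=expected,
        chi2=float(chi2),
        dof=int(dof),
        p_value=float(p),
        yates=yates,
    )
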