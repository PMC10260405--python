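"""Causal-gene prioritization from per-gene evidence codes.

Each candidate gene at a locus carries a subset of the evidence codes
{h, r, e, p, m, c, E, P}: gene hit/close by, regulated gene, cis eQTL,
cis pQTL, missense variant, monogenic disease gene, expression
colocalization and protein colocalization.  The score sums the codes with
E/e and P/p each counting once; the highest score wins, and ties are
resolved by a fixed cascade: expression coloc, protein coloc, matching
inborn error of metabolism, Ee over E alone, Pp over P alone, then
smallest distance to the index SNP, with a final deterministic
lexicographic fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_CODES = frozenset("hrepmcEP")


@dataclass
class GeneEvidence:
    """Evidence for one candidate gene at one locus."""

    gene: str
    codes: frozenset[str]
    distance: float  # bp from index SNP to gene body; inf if other chromosome
    inborn_error_match: bool = False

    def __post_init__(self) -> None:
        codes = frozenset(self.codes)
        bad = codes - VALID_CODES
        if bad:
            raise ValueError(f"unknown evidence codes {sorted(bad)} for {self.gene}")
        object.__setattr__(self, "codes", codes)
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


@dataclass
class GeneScore:
    """Score plus the ordered trace of tie-break rules that were applied."""

    gene: str
    score: int
    deciding_rule: str = ""
    trace: list[str] = field(default_factory=list)


def score(evidence: GeneEvidence) -> int:
    """Sum of evidence codes with Ee and Pp each counted once."""
    c = evidence.codes
    s = sum(1 for code in "hrmc" if code in c)
    s += 1 if ("e" in c or "E" in c) else 0
    s += 1 if ("p" in c or "P" in c) else 0
    return s


def distance_to_gene(snp_pos: int, gene_start: int, gene_end: int) -> int:
    """bp gap from SNP to gene body; 0 when the SNP lies inside it."""
    if gene_start <= snp_pos <= gene_end:
        return 0
    return min(abs(snp_pos - gene_start), abs(snp_pos - gene_end))


_RULES = (
    ("expression_coloc", lambda e: "E" in e.codes),
    ("protein_coloc", lambda e: "P" in e.codes),
    ("inborn_error", lambda e: e.inborn_error_match),
    ("Ee_over_E", lambda e: {"E", "e"} <= e.codes),
    ("Pp_over_P", lambda e: {"P", "p"} <= e.codes),
)


def score_genes(evidence: list[GeneEvidence]) -> tuple[GeneScore, list[GeneScore]]:
    """Rank candidates; returns (winner, full ranked list).

    The winner's ``deciding_rule`` names the first cascade rule that
    separated it from the runners-up ("score" when the score alone
    decided, empty for a singleton candidate list).
    """
    if not evidence:
        raise ValueError("no candidate genes supplied")
    scored = {e.gene: score(e) for e in evidence}
    ranked: list[GeneScore] = []

    if len(evidence) == 1:
        winner = GeneScore(gene=evidence[0].gene, score=scored[evidence[0].gene])
        return winner, [winner]

    top = max(scored.values())
    contenders = [e for e in evidence if scored[e.gene] == top]
    trace: list[str] = []
    deciding = "score"
    for rule_name, pred in _RULES:
        if len(contenders) == 1:
            break
        hits = [e for e in contenders if pred(e)]
        if hits and len(hits) < len(contenders):
            contenders = hits
            trace.append(rule_name)
            deciding = rule_name
    if len(contenders) > 1:
        dmin = min(e.distance for e in contenders)
        closest = [e for e in contenders if e.distance == dmin]
        if len(closest) < len(contenders):
            trace.append("distance")
            deciding = "distance"
        contenders = closest
    if len(contenders) > 1:
        contenders = [min(contenders, key=lambda e: e.gene)]
        trace.append("lexicographic")
        deciding = "lexicographic"

    winner_ev = contenders[0]
    order = sorted(
        evidence, key=lambda e: (-scored[e.gene], e.gene != winner_ev.gene, e.gene)
    )
    for e in order:
        gs = GeneScore(gene=e.gene, score=scored[e.gene])
        if e.gene == winner_ev.gene:
            gs.deciding_rule = deciding
            gs.trace = trace
        ranked.append(gs)
    return ranked[0], ranked
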