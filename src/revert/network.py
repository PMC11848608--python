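"""Boolean gene-regulatory networks: rules, signed skeletons, and file formats.

A :class:`BooleanNetwork` is the simulatable object at the center of the
package: named genes, one Boolean update rule per gene, synchronous dynamics.
Rules are stored as explicit truth tables over an ordered regulator list,
which makes scoring against data, monotonicity checks and rule perturbation
(random permutation of a table's output column) trivial.

Truth-table convention: for regulators ``(r_0, ..., r_{R-1})`` the table index
of an input state is ``sum(v[r_j] << (R-1-j))``, i.e. the first regulator is
the most significant bit.  A rule with zero regulators is a constant.

File formats:

* BoolNet-style rule text — header line ``targets, factors`` then one
  ``GENE, <expression>`` per line using ``!``, ``&``, ``|`` and parentheses.
  Writing produces a canonical full-minterm DNF so that write→read→write is
  byte-identical.
* SIF-like signed edge list — ``source<TAB>sign<TAB>target`` with sign in
  ``{+, -, +1, -1, activates, inhibits}``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "BooleanRule",
    "BooleanNetwork",
    "SignedNetwork",
    "rule_from_expression",
    "rule_to_expression",
    "read_boolnet",
    "write_boolnet",
    "read_sif",
    "write_sif",
]


@dataclass(frozen=True)
class BooleanRule:
    """A per-gene Boolean update rule as an explicit truth table.

    Parameters
    ----------
    gene : str
        Target gene name.
    regulators : tuple of str
        Ordered regulator names; may include ``gene`` itself (self-loop).
    table : tuple of int
        Output column of length ``2**len(regulators)`` (``(c,)`` for a
        constant rule), indexed with the first regulator as the most
        significant bit.
    score : int or None
        Data-fit score (number of input-output pairs reproduced), set by
        rule inference.
    provenance : tuple of tuple of int
        The tied optimal tables that were OR-combined into this rule;
        empty when the optimum was unique.
    """

    gene: str
    regulators: tuple[str, ...]
    table: tuple[int, ...]
    score: int | None = None
    provenance: tuple[tuple[int, ...], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.table) != 2 ** len(self.regulators):
            raise ValueError(
                f"rule for {self.gene!r}: table length {len(self.table)} "
                f"!= 2^{len(self.regulators)}"
            )
        if any(b not in (0, 1) for b in self.table):
            raise ValueError(f"rule for {self.gene!r}: non-binary table entry")

    @property
    def n_regulators(self) -> int:
        return len(self.regulators)

    def evaluate(self, inputs: dict[str, int]) -> int:
        """Evaluate the rule on a mapping of regulator name -> 0/1."""
        idx = 0
        for r in self.regulators:
            idx = (idx << 1) | (inputs[r] & 1)
        return self.table[idx]


@dataclass(frozen=True)
class BooleanNetwork:
    """Named genes plus one :class:`BooleanRule` per gene."""

    genes: tuple[str, ...]
    rules: dict[str, BooleanRule]

    def __post_init__(self) -> None:
        missing = [g for g in self.genes if g not in self.rules]
        if missing:
            raise ValueError(f"genes without rules: {missing}")
        for g, rule in self.rules.items():
            unknown = [r for r in rule.regulators if r not in self.genes]
            if unknown:
                raise ValueError(f"rule for {g!r} uses unknown regulators {unknown}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def index(self, gene: str) -> int:
        return self.genes.index(gene)

    def step(self, state: tuple[int, ...]) -> tuple[int, ...]:
        """One synchronous update: every gene updated simultaneously."""
        if len(state) != self.n_genes:
            raise ValueError("state length does not match network size")
        values = dict(zip(self.genes, state))
        return tuple(self.rules[g].evaluate(values) for g in self.genes)

    def with_rule(self, rule: BooleanRule) -> "BooleanNetwork":
        new = dict(self.rules)
        new[rule.gene] = rule
        return BooleanNetwork(self.genes, new)

    def signed_edges(self) -> list[tuple[str, str, int]]:
        """Regulator->target edges with the sign implied by each rule's
        monotone direction (+1 non-decreasing, -1 non-increasing; 0 if the
        rule is not monotone in that regulator)."""
        out = []
        for g in self.genes:
            rule = self.rules[g]
            for j, r in enumerate(rule.regulators):
                out.append((r, g, _monotone_sign(rule.table, j, rule.n_regulators)))
        return out


def _monotone_sign(table: tuple[int, ...], j: int, n: int) -> int:
    """Sign of regulator j in an n-input table: +1/-1 if monotone, else 0."""
    inc = dec = True
    bit = 1 << (n - 1 - j)
    for idx in range(len(table)):
        if idx & bit:
            lo, hi = table[idx ^ bit], table[idx]
            if lo > hi:
                inc = False
            if lo < hi:
                dec = False
    if inc and dec:  # regulator inessential
        return 0
    return 1 if inc else (-1 if dec else 0)


# ---------------------------------------------------------------------------
# signed skeleton


@dataclass
class SignedNetwork:
    """A signed directed interaction network (the GRN skeleton).

    Edges are ``(source, target) -> sign`` with sign in ``{+1, -1}``;
    ``nodes`` may include isolated genes.
    """

    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        for (u, v), s in self.edges.items():
            if s not in (1, -1):
                raise ValueError(f"edge ({u},{v}) has sign {s}, expected +-1")
        node_set = set(self.nodes)
        for u, v in self.edges:
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u},{v}) references unknown node")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def regulators_of(self, gene: str) -> list[tuple[str, int]]:
        """(source, sign) pairs feeding into ``gene``, in node order."""
        order = {g: i for i, g in enumerate(self.nodes)}
        found = [(u, s) for (u, v), s in self.edges.items() if v == gene]
        return sorted(found, key=lambda us: order[us[0]])

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (u, v), s in self.edges.items():
            g.add_edge(u, v, sign=s)
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "SignedNetwork":
        return cls(
            nodes=tuple(g.nodes),
            edges={(u, v): d["sign"] for u, v, d in g.edges(data=True)},
        )

    def subnetwork(self, keep: set[str]) -> "SignedNetwork":
        return SignedNetwork(
            nodes=tuple(n for n in self.nodes if n in keep),
            edges={(u, v): s for (u, v), s in self.edges.items()
                   if u in keep and v in keep},
        )


# ---------------------------------------------------------------------------
# BoolNet-style rule text

_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_.]*")

_TOKEN_RE = re.compile(r"\s*(?:([A-Za-z_][A-Za-z0-9_.]*)|([01])|([!&|()]))")


class _ExprParser:
    """Recursive-descent parser for `!`/`&`/`|` Boolean expressions.

    Precedence: ! > & > |.  Records variables in order of first appearance,
    which fixes the regulator order of the resulting rule.
    """

    def __init__(self, text: str):
        self.tokens: list[str] = []
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if m is None:
                if text[pos:].strip():
                    raise ValueError(f"cannot tokenize rule expression: {text!r}")
                break
            self.tokens.append(m.group(0).strip())
            pos = m.end()
        self.i = 0
        self.variables: list[str] = []

    def _peek(self) -> str | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self) -> str:
        tok = self._peek()
        if tok is None:
            raise ValueError("unexpected end of rule expression")
        self.i += 1
        return tok

    def parse(self):
        node = self._or()
        if self._peek() is not None:
            raise ValueError(f"trailing tokens in rule expression: {self.tokens[self.i:]}")
        return node

    def _or(self):
        left = self._and()
        while self._peek() == "|":
            self._next()
            right = self._and()
            left = ("or", left, right)
        return left

    def _and(self):
        left = self._not()
        while self._peek() == "&":
            self._next()
            right = self._not()
            left = ("and", left, right)
        return left

    def _not(self):
        if self._peek() == "!":
            self._next()
            return ("not", self._not())
        return self._atom()

    def _atom(self):
        tok = self._next()
        if tok == "(":
            node = self._or()
            if self._next() != ")":
                raise ValueError("unbalanced parentheses in rule expression")
            return node
        if tok in ("0", "1"):
            return ("const", int(tok))
        if _NAME_RE.fullmatch(tok):
            if tok not in self.variables:
                self.variables.append(tok)
            return ("var", tok)
        raise ValueError(f"unexpected token {tok!r}")


def _eval_node(node, env: dict[str, int]) -> int:
    kind = node[0]
    if kind == "const":
        return node[1]
    if kind == "var":
        return env[node[1]]
    if kind == "not":
        return 1 - _eval_node(node[1], env)
    a, b = _eval_node(node[1], env), _eval_node(node[2], env)
    return (a & b) if kind == "and" else (a | b)


def rule_from_expression(gene: str, expr: str) -> BooleanRule:
    """Parse a BoolNet-style expression into a truth-table rule.

    Regulator order is the order of first appearance in the expression.
    """
    parser = _ExprParser(expr)
    node = parser.parse()
    regs = tuple(parser.variables)
    n = len(regs)
    table = []
    for idx in range(2 ** n):
        env = {r: (idx >> (n - 1 - j)) & 1 for j, r in enumerate(regs)}
        table.append(_eval_node(node, env))
    return BooleanRule(gene=gene, regulators=regs, table=tuple(table))


def rule_to_expression(rule: BooleanRule) -> str:
    """Canonical full-minterm DNF (or '0'/'1' for constants).

    Every regulator appears in every minterm, in the rule's regulator order,
    so parsing the output reconstructs the same regulator tuple and table.
    """
    n = rule.n_regulators
    if n == 0 or all(b == rule.table[0] for b in rule.table):
        return str(rule.table[0])
    terms = []
    for idx, out in enumerate(rule.table):
        if not out:
            continue
        lits = []
        for j, r in enumerate(rule.regulators):
            bit = (idx >> (n - 1 - j)) & 1
            lits.append(r if bit else f"!{r}")
        terms.append("(" + " & ".join(lits) + ")")
    return " | ".join(terms)


def write_boolnet(net: BooleanNetwork) -> str:
    """Serialize to BoolNet-style rule text ('targets, factors' header)."""
    lines = ["targets, factors"]
    for g in net.genes:
        lines.append(f"{g}, {rule_to_expression(net.rules[g])}")
    return "\n".join(lines) + "\n"


def read_boolnet(text: str) -> BooleanNetwork:
    """Parse BoolNet-style rule text into a :class:`BooleanNetwork`.

    Constant rules ('GENE, 0' / 'GENE, 1') become zero-regulator rules.
    """
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines or lines[0].replace(" ", "").lower() != "targets,factors":
        raise ValueError("rule file must start with a 'targets, factors' header")
    genes: list[str] = []
    rules: dict[str, BooleanRule] = {}
    for ln in lines[1:]:
        if "," not in ln:
            raise ValueError(f"malformed rule line: {ln!r}")
        gene, expr = ln.split(",", 1)
        gene = gene.strip()
        rules[gene] = rule_from_expression(gene, expr.strip())
        genes.append(gene)
    net = BooleanNetwork(tuple(genes), rules)
    return net


_SIGN_ALIASES = {
    "+": 1, "-": -1, "+1": 1, "-1": -1, "1": 1,
    "activates": 1, "inhibits": -1, "activation": 1, "inhibition": -1,
}


def write_sif(net: SignedNetwork) -> str:
    """source<TAB>sign<TAB>target lines, '+'/'-' signs, edge-dict order."""
    lines = [f"{u}\t{'+' if s > 0 else '-'}\t{v}" for (u, v), s in net.edges.items()]
    return "\n".join(lines) + ("\n" if lines else "")


def read_sif(text: str) -> SignedNetwork:
    """Parse a 3-column signed edge list (whitespace- or tab-separated)."""
    nodes: list[str] = []
    edges: dict[tuple[str, str], int] = {}

    def add_node(n: str) -> None:
        if n not in nodes:
            nodes.append(n)

    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split()
        if len(parts) != 3:
            raise ValueError(f"expected 3 columns in edge line: {ln!r}")
        u, sign_s, v = parts
        sign = _SIGN_ALIASES.get(sign_s.lower())
        if sign is None:
            raise ValueError(f"unknown interaction sign {sign_s!r}")
        add_node(u)
        add_node(v)
        edges[(u, v)] = sign
    return SignedNetwork(tuple(nodes), edges)


def network_from_signed(skeleton: SignedNetwork,
                        tables: dict[str, tuple[int, ...]]) -> BooleanNetwork:
    """Assemble a BooleanNetwork from a skeleton plus per-gene tables.

    Regulator order per gene follows :meth:`SignedNetwork.regulators_of`.
    """
    rules = {}
    for g in skeleton.nodes:
        regs = tuple(u for u, _ in skeleton.regulators_of(g))
        rules[g] = BooleanRule(gene=g, regulators=regs, table=tuple(tables[g]))
    return BooleanNetwork(skeleton.nodes, rules)
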