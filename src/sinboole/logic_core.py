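"""Boolean expressions and networks: representation, parsing, validation, serialization.

A :class:`BooleanNetwork` is a set of named nodes, a subset of which are
*inputs* (no update rule; their value is supplied externally, typically by a
clamp), while every other node carries exactly one update rule — a Boolean
expression over declared node names built from AND, OR and NOT. This is the
standard logical-model formalism for gene regulatory networks: a node is 1
("active") or 0 ("inactive") and its next value is its rule evaluated on the
current network state.

The native rule dialect is line-oriented::

    # comment
    input Cdc42
    Byr4 := NOT Cdc42

Keywords AND/OR/NOT are case-insensitive; parentheses group; the constants
``0`` and ``1`` are legal sub-expressions (useful for clamped
simplifications). Node identifiers may contain letters, digits, ``_`` and
``-`` (complex names such as ``Sid1-Cdc14`` or ``CDK-0`` are single
identifiers; there is no arithmetic, so ``-`` is unambiguous).

Two further round-trippable dialects are supported: a BoolNet-style
``targets, factors`` table using ``&``/``|``/``!``, and a versioned JSON
schema. SBML-qual (Level 3) is export-only.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence
from xml.etree import ElementTree as ET

__all__ = [
    "BooleanExpression",
    "Var",
    "Const",
    "Not",
    "And",
    "Or",
    "BooleanNetwork",
    "ValidationIssue",
    "ValidationReport",
    "RuleSyntaxError",
    "parse_expression",
    "parse_rules",
    "evaluate",
    "validate",
    "serialize_network",
    "parse_network",
    "truth_table",
    "expressions_equivalent",
]


# ---------------------------------------------------------------------------
# Expression AST
# ---------------------------------------------------------------------------

class BooleanExpression:
    """Base class for expression-tree nodes. Immutable and hashable."""

    __slots__ = ()

    def evaluate(self, state: Mapping[str, int]) -> int:
        raise NotImplementedError

    def variables(self) -> frozenset[str]:
        raise NotImplementedError

    def to_native(self) -> str:
        """Render in the native dialect (AND/OR/NOT, parenthesized)."""
        raise NotImplementedError

    def to_infix(self, and_op: str = "AND", or_op: str = "OR", not_op: str = "NOT ") -> str:
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self.to_native()!r})"


@dataclass(frozen=True, slots=True)
class Var(BooleanExpression):
    name: str

    def evaluate(self, state: Mapping[str, int]) -> int:
        try:
            return 1 if state[self.name] else 0
        except KeyError:
            raise KeyError(f"state does not assign variable {self.name!r}") from None

    def variables(self) -> frozenset[str]:
        return frozenset({self.name})

    def to_native(self) -> str:
        return self.name

    def to_infix(self, and_op: str = "AND", or_op: str = "OR", not_op: str = "NOT ") -> str:
        return self.name


@dataclass(frozen=True, slots=True)
class Const(BooleanExpression):
    value: int

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError(f"Boolean constant must be 0 or 1, got {self.value!r}")

    def evaluate(self, state: Mapping[str, int]) -> int:
        return self.value

    def variables(self) -> frozenset[str]:
        return frozenset()

    def to_native(self) -> str:
        return str(self.value)

    def to_infix(self, and_op: str = "AND", or_op: str = "OR", not_op: str = "NOT ") -> str:
        return str(self.value)


@dataclass(frozen=True, slots=True)
class Not(BooleanExpression):
    child: BooleanExpression

    def evaluate(self, state: Mapping[str, int]) -> int:
        return 1 - self.child.evaluate(state)

    def variables(self) -> frozenset[str]:
        return self.child.variables()

    def to_native(self) -> str:
        return self.to_infix()

    def to_infix(self, and_op: str = "AND", or_op: str = "OR", not_op: str = "NOT ") -> str:
        inner = self.child.to_infix(and_op, or_op, not_op)
        if isinstance(self.child, (And, Or)):
            inner = f"({inner})"
        return f"{not_op}{inner}"


def _nary_init(cls_name: str, children: Sequence[BooleanExpression]) -> tuple[BooleanExpression, ...]:
    children = tuple(children)
    if len(children) < 2:
        raise ValueError(f"{cls_name} requires at least 2 operands, got {len(children)}")
    return children


@dataclass(frozen=True, slots=True)
class And(BooleanExpression):
    children: tuple[BooleanExpression, ...]

    def __init__(self, children: Sequence[BooleanExpression]):
        object.__setattr__(self, "children", _nary_init("And", children))

    def evaluate(self, state: Mapping[str, int]) -> int:
        for c in self.children:
            if not c.evaluate(state):
                return 0
        return 1

    def variables(self) -> frozenset[str]:
        return frozenset().union(*(c.variables() for c in self.children))

    def to_native(self) -> str:
        return self.to_infix()

    def to_infix(self, and_op: str = "AND", or_op: str = "OR", not_op: str = "NOT ") -> str:
        parts = []
        for c in self.children:
            s = c.to_infix(and_op, or_op, not_op)
            if isinstance(c, Or):
                s = f"({s})"
            parts.append(s)
        return f" {and_op} ".join(parts)


@dataclass(frozen=True, slots=True)
class Or(BooleanExpression):
    children: tuple[BooleanExpression, ...]

    def __init__(self, children: Sequence[BooleanExpression]):
        object.__setattr__(self, "children", _nary_init("Or", children))

    def evaluate(self, state: Mapping[str, int]) -> int:
        for c in self.children:
            if c.evaluate(state):
                return 1
        return 0

    def variables(self) -> frozenset[str]:
        return frozenset().union(*(c.variables() for c in self.children))

    def to_native(self) -> str:
        return self.to_infix()

    def to_infix(self, and_op: str = "AND", or_op: str = "OR", not_op: str = "NOT ") -> str:
        parts = []
        for c in self.children:
            s = c.to_infix(and_op, or_op, not_op)
            if isinstance(c, And):
                s = f"({s})"  # explicit even though AND binds tighter: readability
            parts.append(s)
        return f" {or_op} ".join(parts)


def evaluate(expr: BooleanExpression, state: Mapping[str, int]) -> int:
    """Evaluate ``expr`` under a total assignment. Pure; raises on a missing variable."""
    return expr.evaluate(state)


# ---------------------------------------------------------------------------
# Tokenizer / recursive-descent parser
# ---------------------------------------------------------------------------

class RuleSyntaxError(ValueError):
    """Syntax or reference error in a rule file; carries line and column."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (f", column {column}" if column is not None else "") + ")"
        super().__init__(message + loc)
        self.line = line
        self.column = column


_IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_\-]*")
_KEYWORDS = {"and": "AND", "or": "OR", "not": "NOT"}

Token = tuple[str, str, int]  # (kind, text, column)


def _tokenize(text: str, line_no: int) -> list[Token]:
    tokens: list[Token] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch in " \t":
            i += 1
            continue
        if ch == "#":
            break
        if ch == "(":
            tokens.append(("LPAREN", ch, i)); i += 1
        elif ch == ")":
            tokens.append(("RPAREN", ch, i)); i += 1
        else:
            # identifiers cannot start with a digit, so a leading 0/1 here is
            # always a constant; digits inside names are consumed by the match
            m = _IDENT_RE.match(text, i)
            if m:
                word = m.group(0)
                kind = _KEYWORDS.get(word.lower(), "IDENT")
                tokens.append((kind, word, i))
                i = m.end()
            elif ch in "01":
                tokens.append(("CONST", ch, i)); i += 1
            else:
                raise RuleSyntaxError(f"unexpected character {ch!r}", line_no, i + 1)
    return tokens


class _ExprParser:
    """Precedence: NOT > AND > OR. Grammar::

        expr   : term (OR term)*
        term   : factor (AND factor)*
        factor : NOT factor | '(' expr ')' | IDENT | CONST
    """

    def __init__(self, tokens: list[Token], line_no: int):
        self.tokens = tokens
        self.pos = 0
        self.line_no = line_no

    def _peek(self) -> Token | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self) -> Token:
        tok = self._peek()
        if tok is None:
            raise RuleSyntaxError("unexpected end of expression", self.line_no)
        self.pos += 1
        return tok

    def parse(self) -> BooleanExpression:
        expr = self._expr()
        tok = self._peek()
        if tok is not None:
            raise RuleSyntaxError(f"unexpected token {tok[1]!r}", self.line_no, tok[2] + 1)
        return expr

    def _expr(self) -> BooleanExpression:
        terms = [self._term()]
        while (tok := self._peek()) is not None and tok[0] == "OR":
            self._next()
            terms.append(self._term())
        return terms[0] if len(terms) == 1 else Or(terms)

    def _term(self) -> BooleanExpression:
        factors = [self._factor()]
        while (tok := self._peek()) is not None and tok[0] == "AND":
            self._next()
            factors.append(self._factor())
        return factors[0] if len(factors) == 1 else And(factors)

    def _factor(self) -> BooleanExpression:
        tok = self._next()
        kind, text, col = tok
        if kind == "NOT":
            return Not(self._factor())
        if kind == "LPAREN":
            inner = self._expr()
            closing = self._peek()
            if closing is None or closing[0] != "RPAREN":
                raise RuleSyntaxError("missing closing parenthesis", self.line_no, col + 1)
            self._next()
            return inner
        if kind == "IDENT":
            return Var(text)
        if kind == "CONST":
            return Const(int(text))
        raise RuleSyntaxError(f"unexpected token {text!r}", self.line_no, col + 1)


def parse_expression(text: str, line_no: int = 1) -> BooleanExpression:
    """Parse a single Boolean expression in the native dialect."""
    tokens = _tokenize(text, line_no)
    if not tokens:
        raise RuleSyntaxError("empty expression", line_no)
    return _ExprParser(tokens, line_no).parse()


# ---------------------------------------------------------------------------
# BooleanNetwork
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BooleanNetwork:
    """A Boolean network: ordered node names, input subset, one rule per non-input.

    ``nodes`` fixes the canonical node order used for state tuples and
    serialization. ``inputs`` have no rule; every other node maps to exactly
    one :class:`BooleanExpression` in ``rules``. ``annotations`` optionally
    carries a provenance note per rule (e.g. the literature support for an
    edge); it never affects semantics.
    """

    nodes: tuple[str, ...]
    inputs: frozenset[str]
    rules: Mapping[str, BooleanExpression]
    name: str = ""
    annotations: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "inputs", frozenset(self.inputs))
        object.__setattr__(self, "rules", dict(self.rules))
        object.__setattr__(self, "annotations", dict(self.annotations))
        seen = set()
        for n in self.nodes:
            if not n:
                raise ValueError("node names must be non-empty")
            if n in seen:
                raise ValueError(f"duplicate node name {n!r}")
            seen.add(n)
        unknown_inputs = self.inputs - seen
        if unknown_inputs:
            raise ValueError(f"input nodes not declared: {sorted(unknown_inputs)}")
        for n in self.inputs:
            if n in self.rules:
                raise ValueError(f"input node {n!r} must not have a rule")
        for n in self.nodes:
            if n not in self.inputs and n not in self.rules:
                raise ValueError(f"non-input node {n!r} has no rule")
        for n in self.rules:
            if n not in seen:
                raise ValueError(f"rule for undeclared node {n!r}")
        for n, expr in self.rules.items():
            undeclared = expr.variables() - seen
            if undeclared:
                raise ValueError(
                    f"rule for {n!r} references undeclared node(s): {sorted(undeclared)}"
                )

    @property
    def free_nodes(self) -> tuple[str, ...]:
        """Nodes carrying a rule (i.e. non-inputs), in canonical order."""
        return tuple(n for n in self.nodes if n not in self.inputs)

    def regulators(self, node: str) -> frozenset[str]:
        """Nodes appearing in ``node``'s rule; empty for inputs/constants."""
        expr = self.rules.get(node)
        return expr.variables() if expr is not None else frozenset()

    def in_degree(self, node: str) -> int:
        return len(self.regulators(node))

    def with_rule(self, node: str, expr: BooleanExpression) -> "BooleanNetwork":
        """Copy of the network with one rule replaced (node must be non-input)."""
        if node in self.inputs:
            raise ValueError(f"cannot assign a rule to input node {node!r}")
        if node not in self.rules:
            raise ValueError(f"node {node!r} has no rule to replace")
        rules = dict(self.rules)
        rules[node] = expr
        return BooleanNetwork(self.nodes, self.inputs, rules, self.name, self.annotations)

    def __iter__(self) -> Iterator[str]:
        return iter(self.nodes)


# ---------------------------------------------------------------------------
# Rule-file parsing (native dialect)
# ---------------------------------------------------------------------------

def parse_rules(text: str, name: str = "") -> BooleanNetwork:
    """Parse a native-dialect rule file into a validated :class:`BooleanNetwork`.

    One statement per line: ``input <node>`` declares an input,
    ``<node> := <expr>`` gives a rule. Declaration order fixes the canonical
    node order; rule order is otherwise irrelevant to semantics. ``#`` starts
    a comment. Errors (syntax, undeclared reference, duplicate rule) raise
    :class:`RuleSyntaxError`.
    """
    nodes: list[str] = []
    inputs: set[str] = set()
    rules: dict[str, BooleanExpression] = {}
    annotations: dict[str, str] = {}

    for line_no, raw in enumerate(text.splitlines(), start=1):
        comment = ""
        if "#" in raw:
            raw, comment = raw.split("#", 1)
            comment = comment.strip()
        line = raw.strip()
        if not line:
            continue
        m = re.match(r"^input\s+(\S+)\s*$", line, flags=re.IGNORECASE)
        if m:
            node = m.group(1)
            if not _IDENT_RE.fullmatch(node):
                raise RuleSyntaxError(f"invalid node name {node!r}", line_no)
            if node in nodes:
                raise RuleSyntaxError(f"duplicate declaration of {node!r}", line_no)
            nodes.append(node)
            inputs.add(node)
            continue
        if ":=" not in line:
            raise RuleSyntaxError("expected 'input <node>' or '<node> := <expr>'", line_no)
        lhs, rhs = line.split(":=", 1)
        node = lhs.strip()
        if not _IDENT_RE.fullmatch(node):
            raise RuleSyntaxError(f"invalid node name {node!r} on left-hand side", line_no)
        if node in rules:
            raise RuleSyntaxError(f"duplicate rule for node {node!r}", line_no)
        if node in inputs:
            raise RuleSyntaxError(f"node {node!r} declared as input but given a rule", line_no)
        if node not in nodes:
            nodes.append(node)
        rules[node] = parse_expression(rhs, line_no)
        if comment:
            annotations[node] = comment

    declared = set(nodes)
    for node, expr in rules.items():
        undeclared = expr.variables() - declared
        if undeclared:
            raise RuleSyntaxError(
                f"rule for {node!r} references undeclared node(s): {sorted(undeclared)}"
            )
    return BooleanNetwork(tuple(nodes), frozenset(inputs), rules, name, annotations)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    node: str
    message: str


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[ValidationIssue, ...]

    @property
    def errors(self) -> tuple[ValidationIssue, ...]:
        return tuple(i for i in self.issues if i.severity == "error")

    @property
    def warnings(self) -> tuple[ValidationIssue, ...]:
        return tuple(i for i in self.issues if i.severity == "warning")

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_errors(self) -> None:
        if self.errors:
            msgs = "; ".join(f"{i.node}: {i.message}" for i in self.errors)
            raise ValueError(f"invalid network: {msgs}")


def validate(network: BooleanNetwork) -> ValidationReport:
    """Structural validation beyond the constructor invariants.

    Errors: rule referencing an undeclared node; a node that is neither input
    nor ruled (both normally impossible after construction, but checked for
    networks built by hand). Warnings: a rule that is constant over all
    assignments of its variables; a declared node regulating nothing and
    regulated by nothing.
    """
    issues: list[ValidationIssue] = []
    declared = set(network.nodes)
    for node in network.nodes:
        if node not in network.inputs and node not in network.rules:
            issues.append(ValidationIssue("error", node, "no rule and not declared as input"))
    for node, expr in network.rules.items():
        undeclared = expr.variables() - declared
        for miss in sorted(undeclared):
            issues.append(ValidationIssue("error", node, f"rule references undeclared node {miss!r}"))
        if not undeclared:
            vs = sorted(expr.variables())
            values = {
                expr.evaluate(dict(zip(vs, bits)))
                for bits in _all_bit_tuples(len(vs))
            }
            if len(values) == 1:
                issues.append(
                    ValidationIssue(
                        "warning", node, f"rule is constant {values.pop()} over all inputs"
                    )
                )
    referenced = set().union(*(e.variables() for e in network.rules.values())) if network.rules else set()
    for node in network.nodes:
        if node not in referenced and node not in network.rules:
            issues.append(ValidationIssue("warning", node, "input node is never referenced"))
    return ValidationReport(tuple(issues))


def _all_bit_tuples(n: int):
    for i in range(1 << n):
        yield tuple((i >> j) & 1 for j in range(n))


def truth_table(expr: BooleanExpression, variables: Sequence[str]) -> tuple[int, ...]:
    """Truth table of ``expr`` over the given variable order (LSB = first variable)."""
    vs = list(variables)
    return tuple(
        expr.evaluate(dict(zip(vs, bits))) for bits in _all_bit_tuples(len(vs))
    )


def expressions_equivalent(a: BooleanExpression, b: BooleanExpression) -> bool:
    """Semantic (truth-table) equality over the union of the two variable sets."""
    vs = sorted(a.variables() | b.variables())
    return truth_table(a, vs) == truth_table(b, vs)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_JSON_SCHEMA_VERSION = 1
DIALECTS = ("native", "bnet", "json", "sbml-qual")


def serialize_network(network: BooleanNetwork, dialect: str = "native") -> str:
    """Serialize to ``native``, ``bnet``, ``json`` or ``sbml-qual`` text.

    native/bnet/json round-trip through :func:`parse_network` with per-node
    truth tables preserved; sbml-qual is export-only.
    """
    if dialect == "native":
        return _to_native(network)
    if dialect == "bnet":
        return _to_bnet(network)
    if dialect == "json":
        return _to_json(network)
    if dialect == "sbml-qual":
        return _to_sbml_qual(network)
    raise ValueError(f"unsupported dialect {dialect!r}; choose from {DIALECTS}")


def parse_network(text: str, dialect: str = "native", name: str = "") -> BooleanNetwork:
    """Parse network text in a round-trippable dialect (native, bnet, json)."""
    if dialect == "native":
        return parse_rules(text, name)
    if dialect == "bnet":
        return _from_bnet(text, name)
    if dialect == "json":
        return _from_json(text, name)
    if dialect == "sbml-qual":
        raise ValueError("sbml-qual is export-only")
    raise ValueError(f"unsupported dialect {dialect!r}; choose from {DIALECTS}")


def _to_native(network: BooleanNetwork) -> str:
    lines = []
    if network.name:
        lines.append(f"# {network.name}")
    for node in network.nodes:
        if node in network.inputs:
            lines.append(f"input {node}")
    for node in network.nodes:
        if node in network.inputs:
            continue
        line = f"{node} := {network.rules[node].to_native()}"
        note = network.annotations.get(node)
        if note:
            line += f"  # {note}"
        lines.append(line)
    return "\n".join(lines) + "\n"


def _to_bnet(network: BooleanNetwork) -> str:
    # BoolNet-style "targets, factors"; inputs encoded as self-dependent
    # identity rules, the BoolNet convention for constant-free input nodes.
    lines = ["targets, factors"]
    for node in network.nodes:
        if node in network.inputs:
            lines.append(f"{node}, {node}")
        else:
            factors = network.rules[node].to_infix(and_op="&", or_op="|", not_op="!")
            lines.append(f"{node}, {factors}")
    return "\n".join(lines) + "\n"


def _from_bnet(text: str, name: str = "") -> BooleanNetwork:
    nodes: list[str] = []
    raw_rules: dict[str, str] = {}
    header_seen = False
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not header_seen:
            if re.sub(r"\s", "", line.lower()) != "targets,factors":
                raise RuleSyntaxError("expected 'targets, factors' header", line_no)
            header_seen = True
            continue
        if "," not in line:
            raise RuleSyntaxError("expected '<target>, <factors>'", line_no)
        target, factors = line.split(",", 1)
        target = target.strip()
        if not _IDENT_RE.fullmatch(target):
            raise RuleSyntaxError(f"invalid node name {target!r}", line_no)
        if target in raw_rules:
            raise RuleSyntaxError(f"duplicate rule for node {target!r}", line_no)
        nodes.append(target)
        raw_rules[target] = (factors, line_no)
    inputs: set[str] = set()
    rules: dict[str, BooleanExpression] = {}
    for target, (factors, line_no) in raw_rules.items():
        expr_text = (
            factors.replace("&", " AND ").replace("|", " OR ").replace("!", " NOT ")
        )
        expr = parse_expression(expr_text, line_no)
        if expr == Var(target):
            inputs.add(target)  # identity self-rule = input convention
        else:
            rules[target] = expr
    return BooleanNetwork(tuple(nodes), frozenset(inputs), rules, name)


def _to_json(network: BooleanNetwork) -> str:
    doc = {
        "schema_version": _JSON_SCHEMA_VERSION,
        "name": network.name,
        "nodes": list(network.nodes),
        "inputs": sorted(network.inputs),
        "rules": {n: network.rules[n].to_native() for n in network.nodes if n not in network.inputs},
        "annotations": dict(network.annotations),
    }
    return json.dumps(doc, indent=2) + "\n"


def _from_json(text: str, name: str = "") -> BooleanNetwork:
    doc = json.loads(text)
    version = doc.get("schema_version")
    if version != _JSON_SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {version!r}")
    rules = {n: parse_expression(e) for n, e in doc["rules"].items()}
    return BooleanNetwork(
        tuple(doc["nodes"]),
        frozenset(doc["inputs"]),
        rules,
        doc.get("name", name),
        doc.get("annotations", {}),
    )


_SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
_QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _sbml_id(name: str) -> str:
    # SBML SIds disallow '-'; map to '_' (collision-free for our models).
    return re.sub(r"[^A-Za-z0-9_]", "_", name)


def _mathml(expr: BooleanExpression, parent: ET.Element) -> None:
    q = lambda tag: f"{{{_MATHML_NS}}}{tag}"
    if isinstance(expr, Var):
        ci = ET.SubElement(parent, q("ci"))
        ci.text = f" {_sbml_id(expr.name)} "
    elif isinstance(expr, Const):
        cn = ET.SubElement(parent, q("cn"), {"type": "integer"})
        cn.text = f" {expr.value} "
    else:
        apply = ET.SubElement(parent, q("apply"))
        if isinstance(expr, Not):
            ET.SubElement(apply, q("not"))
            _mathml(expr.child, apply)
        elif isinstance(expr, And):
            ET.SubElement(apply, q("and"))
            for c in expr.children:
                _mathml(c, apply)
        elif isinstance(expr, Or):
            ET.SubElement(apply, q("or"))
            for c in expr.children:
                _mathml(c, apply)
        else:  # pragma: no cover
            raise TypeError(f"unknown expression type {type(expr)}")


def _to_sbml_qual(network: BooleanNetwork) -> str:
    """SBML Level 3 qual export: one qualitativeSpecies per node, one
    transition per rule. Export-only; the MathML function terms use the
    same AND/OR/NOT structure as the rules."""
    ET.register_namespace("", _SBML_NS)
    ET.register_namespace("qual", _QUAL_NS)
    ET.register_namespace("math", _MATHML_NS)
    s = lambda tag: f"{{{_SBML_NS}}}{tag}"
    q = lambda tag: f"{{{_QUAL_NS}}}{tag}"

    sbml = ET.Element(
        s("sbml"),
        {"level": "3", "version": "1", f"{{{_QUAL_NS}}}required": "true"},
    )
    model_id = _sbml_id(network.name) or "model"
    model = ET.SubElement(sbml, s("model"), {"id": model_id})
    comps = ET.SubElement(model, s("listOfCompartments"))
    ET.SubElement(comps, s("compartment"), {"id": "default", "constant": "true"})
    species_list = ET.SubElement(model, q("listOfQualitativeSpecies"))
    for node in network.nodes:
        ET.SubElement(
            species_list,
            q("qualitativeSpecies"),
            {
                f"{{{_QUAL_NS}}}id": _sbml_id(node),
                f"{{{_QUAL_NS}}}name": node,
                f"{{{_QUAL_NS}}}compartment": "default",
                f"{{{_QUAL_NS}}}constant": "true" if node in network.inputs else "false",
                f"{{{_QUAL_NS}}}maxLevel": "1",
            },
        )
    transitions = ET.SubElement(model, q("listOfTransitions"))
    for node in network.nodes:
        if node in network.inputs:
            continue
        expr = network.rules[node]
        tr = ET.SubElement(transitions, q("transition"), {f"{{{_QUAL_NS}}}id": f"tr_{_sbml_id(node)}"})
        if expr.variables():
            inputs_el = ET.SubElement(tr, q("listOfInputs"))
            for reg in sorted(expr.variables()):
                ET.SubElement(
                    inputs_el,
                    q("input"),
                    {
                        f"{{{_QUAL_NS}}}qualitativeSpecies": _sbml_id(reg),
                        f"{{{_QUAL_NS}}}transitionEffect": "none",
                    },
                )
        outputs_el = ET.SubElement(tr, q("listOfOutputs"))
        ET.SubElement(
            outputs_el,
            q("output"),
            {
                f"{{{_QUAL_NS}}}qualitativeSpecies": _sbml_id(node),
                f"{{{_QUAL_NS}}}transitionEffect": "assignmentLevel",
            },
        )
        terms = ET.SubElement(tr, q("listOfFunctionTerms"))
        ET.SubElement(terms, q("defaultTerm"), {f"{{{_QUAL_NS}}}resultLevel": "0"})
        ft = ET.SubElement(terms, q("functionTerm"), {f"{{{_QUAL_NS}}}resultLevel": "1"})
        math = ET.SubElement(ft, f"{{{_MATHML_NS}}}math")
        _mathml(expr, math)
    ET.indent(sbml)
    return ET.tostring(sbml, encoding="unicode", xml_declaration=True) + "\n"
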