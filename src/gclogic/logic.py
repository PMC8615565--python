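"""Multi-valued logical networks: rules, clamps, synchronous update, fixpoints.

A network is a set of named components, each with a discrete activity level
between 0 and ``max_level`` (1 for Boolean components, 2 for ternary ones).
Regulation is written with threshold atoms -- ``X`` reads "activity of X is
at least 1", ``X:2`` reads "at least 2" -- combined with ``!`` (NOT), ``&``
(AND) and ``|`` (OR).  A component that can reach several levels lists one
condition per attainable level; on update it adopts the *highest* level whose
condition is satisfied, or 0 when none is.

Clamps pin a component to a fixed level regardless of its rule; they model
genetic gain/loss of function and pharmacological inhibition.  Input
components have no rule and are held constant at an externally supplied
level, so fixpoint analysis is always conditioned on an input assignment.

The update scheme is synchronous and serves only to define fixpoints
(states ``s`` with ``f(s) == s``), which are invariant across update
schemes; trajectory dynamics and cyclic attractors are out of scope.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence, Union


class DefinitionError(ValueError):
    """A network, expression or clamp violates a structural constraint."""


class UsageError(ValueError):
    """An operation was called with inconsistent or missing arguments."""


class ModelParseError(ValueError):
    """A model-definition file could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


# ---------------------------------------------------------------------------
# Expressions
# ---------------------------------------------------------------------------

class Expression:
    """Base class for rule conditions (threshold atoms under NOT/AND/OR)."""

    __slots__ = ()


@dataclass(frozen=True)
class Atom(Expression):
    """Truth of ``component activity >= threshold``."""

    component: str
    threshold: int = 1

    def __post_init__(self):
        if self.threshold < 1:
            raise DefinitionError(
                f"atom threshold must be >= 1, got {self.component}:{self.threshold}"
            )


@dataclass(frozen=True)
class Not(Expression):
    operand: Expression


@dataclass(frozen=True)
class And(Expression):
    operands: tuple[Expression, ...]


@dataclass(frozen=True)
class Or(Expression):
    operands: tuple[Expression, ...]


def atoms_of(expr: Expression) -> Iterator[Atom]:
    """Yield every atom in ``expr`` (depth-first, duplicates included)."""
    if isinstance(expr, Atom):
        yield expr
    elif isinstance(expr, Not):
        yield from atoms_of(expr.operand)
    elif isinstance(expr, (And, Or)):
        for op in expr.operands:
            yield from atoms_of(op)
    else:  # pragma: no cover - guarded by construction
        raise TypeError(f"not an expression: {expr!r}")


def referenced_components(expr: Expression) -> frozenset[str]:
    return frozenset(a.component for a in atoms_of(expr))


_LevelSource = Union["State", Mapping[str, int]]


def _level(state: _LevelSource, name: str) -> int:
    try:
        return state[name]
    except KeyError:
        raise DefinitionError(f"unknown component {name!r} referenced in expression")


def evaluate_expression(expr: Expression, state: _LevelSource) -> bool:
    """Evaluate a condition against a state (atoms read ``level >= threshold``)."""
    if isinstance(expr, Atom):
        return _level(state, expr.component) >= expr.threshold
    if isinstance(expr, Not):
        return not evaluate_expression(expr.operand, state)
    if isinstance(expr, And):
        return all(evaluate_expression(op, state) for op in expr.operands)
    if isinstance(expr, Or):
        return any(evaluate_expression(op, state) for op in expr.operands)
    raise TypeError(f"not an expression: {expr!r}")


# --- expression text syntax -------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|!|&|\||[A-Za-z][A-Za-z0-9_/.-]*(?::\d+)?)")


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise ModelParseError(f"unexpected character at {text[pos:]!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def parse_expression(text: str) -> Expression:
    """Parse ``!``/``&``/``|`` syntax with atoms ``name`` and ``name:level``.

    Precedence is NOT > AND > OR; parentheses group as usual.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise ModelParseError(f"empty expression in {text!r}")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> Expression:
        terms = [parse_and()]
        while peek() == "|":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and() -> Expression:
        terms = [parse_not()]
        while peek() == "&":
            take()
            terms.append(parse_not())
        return terms[0] if len(terms) == 1 else And(tuple(terms))

    def parse_not() -> Expression:
        tok = peek()
        if tok == "!":
            take()
            return Not(parse_not())
        if tok == "(":
            take()
            inner = parse_or()
            if peek() != ")":
                raise ModelParseError(f"unbalanced parenthesis in {text!r}")
            take()
            return inner
        if tok is None or tok in {")", "&", "|"}:
            raise ModelParseError(f"unexpected token {tok!r} in {text!r}")
        take()
        if ":" in tok:
            name, _, lvl = tok.rpartition(":")
            return Atom(name, int(lvl))
        return Atom(tok)

    expr = parse_or()
    if pos != len(tokens):
        raise ModelParseError(f"trailing tokens {tokens[pos:]} in {text!r}")
    return expr


def expression_to_str(expr: Expression) -> str:
    """Canonical text form (minimal parentheses, ``X:1`` printed as ``X``)."""

    def render(e: Expression, parent: int) -> str:
        # precedence: Or=1, And=2, Not=3, Atom=4
        if isinstance(e, Atom):
            return e.component if e.threshold == 1 else f"{e.component}:{e.threshold}"
        if isinstance(e, Not):
            return "!" + render(e.operand, 3)
        if isinstance(e, And):
            s = " & ".join(render(op, 2) for op in e.operands)
            return f"({s})" if parent > 2 else s
        if isinstance(e, Or):
            s = " | ".join(render(op, 1) for op in e.operands)
            return f"({s})" if parent > 1 else s
        raise TypeError(f"not an expression: {e!r}")

    return render(expr, 0)


# ---------------------------------------------------------------------------
# Components, rules, networks, states
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Component:
    name: str
    max_level: int = 1
    is_input: bool = False

    def __post_init__(self):
        if self.max_level not in (1, 2):
            raise DefinitionError(
                f"component {self.name!r}: max_level must be 1 or 2, got {self.max_level}"
            )


@dataclass(frozen=True)
class LevelRule:
    """Ordered (target_level, condition) pairs for one component.

    Pairs are normalized to descending target level; on update the highest
    satisfied level wins and 0 is the default when no condition holds.
    """

    pairs: tuple[tuple[int, Expression], ...]

    def __post_init__(self):
        pairs = tuple(sorted(self.pairs, key=lambda p: -p[0]))
        levels = [lvl for lvl, _ in pairs]
        if len(set(levels)) != len(levels):
            raise DefinitionError(f"duplicate target levels in rule: {levels}")
        if any(lvl < 1 for lvl in levels):
            raise DefinitionError(f"rule target levels must be >= 1, got {levels}")
        object.__setattr__(self, "pairs", pairs)

    def value(self, state: _LevelSource) -> int:
        for lvl, cond in self.pairs:  # descending
            if evaluate_expression(cond, state):
                return lvl
        return 0

    def referenced(self) -> frozenset[str]:
        return frozenset().union(*(referenced_components(c) for _, c in self.pairs))


@dataclass(frozen=True)
class State:
    """One activity level per component, ordered as the network's components."""

    levels: tuple[int, ...]
    names: tuple[str, ...] = field(repr=False)

    def __post_init__(self):
        if len(self.levels) != len(self.names):
            raise DefinitionError("state length does not match component count")

    def __getitem__(self, name: str) -> int:
        try:
            return self.levels[self.names.index(name)]
        except ValueError:
            raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.names, self.levels))

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(zip(self.names, self.levels))


@dataclass(frozen=True)
class LogicalNetwork:
    """Immutable multi-valued logical network.

    ``rules`` maps every non-input component to its :class:`LevelRule`;
    ``clamps`` maps component names to fixed levels and overrides rules.
    """

    components: tuple[Component, ...]
    rules: Mapping[str, LevelRule]
    clamps: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        components = tuple(self.components)
        object.__setattr__(self, "components", components)
        object.__setattr__(self, "rules", dict(self.rules))
        object.__setattr__(self, "clamps", dict(self.clamps))
        names = [c.name for c in components]
        if len(set(names)) != len(names):
            raise DefinitionError("component names must be unique")
        by_name = {c.name: c for c in components}
        object.__setattr__(self, "_by_name", by_name)
        for comp in components:
            if comp.is_input:
                if comp.name in self.rules:
                    raise DefinitionError(f"input {comp.name!r} must not carry a rule")
            else:
                if comp.name not in self.rules:
                    raise DefinitionError(f"non-input {comp.name!r} lacks a rule")
        for name, rule in self.rules.items():
            if name not in by_name:
                raise DefinitionError(f"rule for unknown component {name!r}")
            comp = by_name[name]
            if comp.max_level == 1 and (
                len(rule.pairs) != 1 or rule.pairs[0][0] != 1
            ):
                raise DefinitionError(
                    f"Boolean component {name!r} needs exactly one rule for level 1"
                )
            for lvl, cond in rule.pairs:
                if lvl > comp.max_level:
                    raise DefinitionError(
                        f"rule level {lvl} exceeds max_level of {name!r}"
                    )
                for atom in atoms_of(cond):
                    if atom.component not in by_name:
                        raise DefinitionError(
                            f"rule of {name!r} references unknown component "
                            f"{atom.component!r}"
                        )
                    if atom.threshold > by_name[atom.component].max_level:
                        raise DefinitionError(
                            f"rule of {name!r}: threshold {atom.threshold} exceeds "
                            f"max_level of {atom.component!r}"
                        )
        for name, lvl in self.clamps.items():
            if name not in by_name:
                raise DefinitionError(f"clamp on unknown component {name!r}")
            if not 0 <= lvl <= by_name[name].max_level:
                raise DefinitionError(
                    f"clamp level {lvl} out of range for {name!r} "
                    f"(max {by_name[name].max_level})"
                )

    # -- introspection ------------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    @property
    def inputs(self) -> tuple[Component, ...]:
        return tuple(c for c in self.components if c.is_input)

    def component(self, name: str) -> Component:
        try:
            return self._by_name[name]
        except KeyError:
            raise DefinitionError(f"unknown component {name!r}")

    def state(self, levels: Mapping[str, int]) -> State:
        """Build a :class:`State` from a name->level mapping (missing -> 0)."""
        vec = []
        for comp in self.components:
            lvl = levels.get(comp.name, 0)
            if not 0 <= lvl <= comp.max_level:
                raise DefinitionError(
                    f"level {lvl} out of range for {comp.name!r}"
                )
            vec.append(lvl)
        return State(tuple(vec), self.names)


def apply_clamps(network: LogicalNetwork, clamps: Mapping[str, int]) -> LogicalNetwork:
    """Return a new network with ``clamps`` merged in (later clamps win).

    The original network is unchanged; clamping the same component twice to
    the same level is idempotent.
    """
    merged = {**network.clamps, **dict(clamps)}
    return replace(network, clamps=merged)


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def target_level(network: LogicalNetwork, name: str, state: _LevelSource) -> int:
    """Level the component moves to: clamp > rule (highest satisfied) > input hold."""
    if name in network.clamps:
        return network.clamps[name]
    comp = network.component(name)
    if comp.is_input:
        return _level(state, name)
    return network.rules[name].value(state)


def synchronous_step(network: LogicalNetwork, state: _LevelSource) -> State:
    """Apply the update function once, all components simultaneously."""
    if not isinstance(state, State):
        state = network.state(dict(state))
    levels = tuple(target_level(network, c.name, state) for c in network.components)
    return State(levels, network.names)


def is_fixpoint(network: LogicalNetwork, state: _LevelSource) -> bool:
    if not isinstance(state, State):
        state = network.state(dict(state))
    return synchronous_step(network, state).levels == state.levels


def propagate_constants(
    network: LogicalNetwork, input_assignment: Mapping[str, int] | None = None
) -> tuple[dict[str, int], list[str]]:
    """Split components into those forced in every fixpoint and the rest.

    Inputs and clamped components are fixed directly; any component whose
    regulators are all fixed is then fixed at its rule value, iterating to a
    fixed point of the propagation.  Returns ``(fixed_levels, free_names)``;
    the free names are exactly the components left undetermined (cyclically
    interdependent and unclamped).
    """
    assignment = dict(input_assignment or {})
    for name in assignment:
        comp = network.component(name)
        if not comp.is_input:
            raise UsageError(f"{name!r} is not an input component")
        if not 0 <= assignment[name] <= comp.max_level:
            raise DefinitionError(f"input level {assignment[name]} out of range for {name!r}")

    fixed: dict[str, int] = {}
    for comp in network.components:
        if comp.name in network.clamps:
            cl = network.clamps[comp.name]
            if comp.is_input and comp.name in assignment and assignment[comp.name] != cl:
                raise UsageError(
                    f"input {comp.name!r} clamped to {cl} but assigned "
                    f"{assignment[comp.name]}"
                )
            fixed[comp.name] = cl
        elif comp.is_input:
            if comp.name not in assignment:
                raise UsageError(f"missing assignment for input {comp.name!r}")
            fixed[comp.name] = assignment[comp.name]

    pending = [c.name for c in network.components if c.name not in fixed]
    refs = {name: network.rules[name].referenced() for name in pending}
    progress = True
    while progress:
        progress = False
        for name in list(pending):
            if refs[name] <= fixed.keys():
                fixed[name] = network.rules[name].value(fixed)
                pending.remove(name)
                progress = True
    return fixed, pending


def enumerate_fixpoints(
    network: LogicalNetwork, input_assignment: Mapping[str, int] | None = None
) -> list[State]:
    """All fixpoints consistent with the input assignment and clamps.

    Components forced by inputs, clamps and constant propagation are pinned;
    the residual (cyclic) components are scanned exhaustively.  Results are
    returned in lexicographic order of the state vector.
    """
    fixed, free = propagate_constants(network, input_assignment)
    ranges = [range(network.component(n).max_level + 1) for n in free]
    results: list[State] = []
    for combo in itertools.product(*ranges):
        full = dict(fixed)
        full.update(zip(free, combo))
        if all(network.rules[n].value(full) == full[n] for n in free):
            results.append(network.state(full))
    results.sort(key=lambda s: s.levels)
    return results


# ---------------------------------------------------------------------------
# Model-definition text format
# ---------------------------------------------------------------------------
#
# One line per component::
#
#     name : max_level : input
#     name : max_level : 2 <- EXPR ; 1 <- EXPR
#
# with an optional trailing `` : clamp=LEVEL`` field.  The writer emits
# components in network order and rule pairs in descending level order, so
# write -> read -> write is byte-stable.

def model_to_text(network: LogicalNetwork) -> str:
    lines = []
    for comp in network.components:
        if comp.is_input:
            third = "input"
        else:
            third = " ; ".join(
                f"{lvl} <- {expression_to_str(cond)}"
                for lvl, cond in network.rules[comp.name].pairs
            )
        line = f"{comp.name} : {comp.max_level} : {third}"
        if comp.name in network.clamps:
            line += f" : clamp={network.clamps[comp.name]}"
        lines.append(line)
    return "\n".join(lines) + "\n"


_FIELD_SPLIT_RE = re.compile(r"\s+:\s+")


def model_from_text(text: str) -> LogicalNetwork:
    components: list[Component] = []
    rules: dict[str, LevelRule] = {}
    clamps: dict[str, int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = _FIELD_SPLIT_RE.split(line)
        if len(parts) == 4:
            m = re.fullmatch(r"clamp=(\d+)", parts[3])
            if not m:
                raise ModelParseError(f"bad clamp field {parts[3]!r}", lineno)
            clamp_level: int | None = int(m.group(1))
            parts = parts[:3]
        else:
            clamp_level = None
        if len(parts) != 3:
            raise ModelParseError(
                f"expected 'name : max_level : input|rule', got {line!r}", lineno
            )
        name, max_level_s, body = parts
        if not re.fullmatch(r"[A-Za-z][A-Za-z0-9_/.-]*", name):
            raise ModelParseError(f"bad component name {name!r}", lineno)
        try:
            max_level = int(max_level_s)
        except ValueError:
            raise ModelParseError(f"bad max_level {max_level_s!r}", lineno)
        is_input = body == "input"
        try:
            components.append(Component(name, max_level, is_input))
            if not is_input:
                pairs = []
                for clause in body.split(" ; "):
                    lvl_s, sep, expr_s = clause.partition("<-")
                    if not sep:
                        raise ModelParseError(f"rule clause missing '<-': {clause!r}", lineno)
                    pairs.append((int(lvl_s.strip()), parse_expression(expr_s.strip())))
                rules[name] = LevelRule(tuple(pairs))
        except (DefinitionError, ModelParseError, ValueError) as exc:
            raise ModelParseError(str(exc), lineno) from exc
        if clamp_level is not None:
            clamps[name] = clamp_level
    return LogicalNetwork(tuple(components), rules, clamps)


def write_model(network: LogicalNetwork, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(model_to_text(network))


def read_model(path) -> LogicalNetwork:
    with open(path, "r", encoding="utf-8") as fh:
        return model_from_text(fh.read())
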