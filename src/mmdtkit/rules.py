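"""Expert rulebase: conjunctive IF-THEN rules over session measurements.

Each rule is a conjunction (optionally a disjunction) of comparisons between
a measured variable and a named normal-range threshold; every rule whose
conditions hold emits its textual clinical finding. Sub-rules attached to a
branch rule (e.g. "placing phase over time") are evaluated only when the
parent fires. The rulebase and the threshold set are plain JSON documents so
clinicians can extend them; the shipped defaults encode the five published
example rules plus a per-disc delay family instantiated for all 60 discs of
each phase.

Normal-range thresholds for kinematic variables default to mean - 2*SD of
the packaged 20-participant healthy-cohort tables (floored at 0): a stated
convention for "the normal range", not a published number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .metrics import column_stats
from .tables import load_fixture

__all__ = [
    "Rule",
    "Finding",
    "RuleBase",
    "Thresholds",
    "default_thresholds",
    "default_rulebase",
    "load_rulebase",
    "evaluate_rules",
    "CONTEXT_VARIABLES",
    "NORMAL_TEXT",
]

COMPARATORS = {
    "<": lambda a, b: a < b,
    ">": lambda a, b: a > b,
    "<=": lambda a, b: a <= b,
    ">=": lambda a, b: a >= b,
}

NORMAL_TEXT = "Normal"

# Vocabulary of measurement variables a rule may reference.
CONTEXT_VARIABLES = (
    {"tt_p", "tt_t", "th_p", "th_t"}
    | {f"rot_{ax}_{ph}" for ax in "rpy" for ph in "pt"}
    | {f"acc_{ax}_{ph}" for ax in "xyz" for ph in "pt"}
    | {f"d{i}_{ph}" for i in range(1, 61) for ph in "pt"}
)


@dataclass(frozen=True)
class Finding:
    rule_id: str
    text: str


@dataclass
class Rule:
    """One IF-THEN rule: comparisons against named thresholds, then a text.

    ``mode`` is "all" (conjunction) or "any" (disjunction over the listed
    comparisons). A rule without text is a pure branch node for its children.
    """

    id: str
    conditions: list[tuple[str, str, str]]  # (variable, comparator, threshold name)
    text: str | None = None
    mode: str = "all"
    children: list["Rule"] = field(default_factory=list)

    def fires(self, ctx: dict, thresholds: "Thresholds") -> bool:
        results = []
        for var, op, thr in self.conditions:
            if var not in ctx or ctx[var] is None:
                results.append(False)
                continue
            results.append(COMPARATORS[op](ctx[var], thresholds[thr]))
        return all(results) if self.mode == "all" else any(results)


@dataclass
class Thresholds:
    """Named normal-range limits referenced by rule conditions."""

    values: dict

    def __getitem__(self, name: str) -> float:
        if name not in self.values:
            raise KeyError(f"threshold {name!r} not defined")
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def replace(self, **overrides) -> "Thresholds":
        vals = dict(self.values)
        vals.update(overrides)
        return Thresholds(vals)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.values, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "Thresholds":
        with open(path) as fh:
            return cls(json.load(fh))


def default_thresholds() -> Thresholds:
    """Shipped defaults.

    Phase time limits: upper 62 s (placing) and 67 s (turning); the lower
    limits are 30 s placeholders (no published value). Kinematic minima are
    mean - 2*SD over the packaged healthy cohort, floored at 0. Inactivity
    and per-disc limits are configurable placeholders.
    """
    vals = {
        "max_t_p": 62.0, "min_t_p": 30.0,
        "max_t_t": 67.0, "min_t_t": 30.0,
        "n_th_p": 10.0, "n_th_t": 10.0,
        "n_d_p": 3.0, "n_d_t": 3.0,
    }
    t5 = load_fixture("table5")
    t6 = load_fixture("table6")
    axis5 = {"r": "roll", "p": "pitch", "y": "yaw"}
    for ax, col in axis5.items():
        for ph, phase in (("p", "placing"), ("t", "turning")):
            st = column_stats(t5[f"{col}_{phase}_dps"])
            vals[f"nrot_{ax}_{ph}"] = max(0.0, st["mean"] - 2 * st["std"])
    for ax in "xyz":
        for ph, phase in (("p", "placing"), ("t", "turning")):
            st = column_stats(t6[f"{ax}_{phase}_ms2"])
            vals[f"nacc_{ax}_{ph}"] = max(0.0, st["mean"] - 2 * st["std"])
    return Thresholds(vals)


@dataclass
class RuleBase:
    rules: list[Rule]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rule in self._walk(self.rules):
            if rule.id in seen:
                raise ValueError(f"duplicate rule id {rule.id!r}")
            seen.add(rule.id)
            if rule.mode not in ("all", "any"):
                raise ValueError(f"rule {rule.id!r}: unknown mode {rule.mode!r}")
            for var, op, thr in rule.conditions:
                if op not in COMPARATORS:
                    raise ValueError(f"rule {rule.id!r}: unknown comparator {op!r}")
                if var not in CONTEXT_VARIABLES:
                    raise ValueError(f"rule {rule.id!r}: undeclared variable {var!r}")

    @staticmethod
    def _walk(rules):
        for r in rules:
            yield r
            yield from RuleBase._walk(r.children)

    def validate_thresholds(self, thresholds: Thresholds) -> None:
        for rule in self._walk(self.rules):
            for _, _, thr in rule.conditions:
                if thr not in thresholds:
                    raise ValueError(
                        f"rule {rule.id!r} references undefined threshold {thr!r}")

    def to_doc(self) -> dict:
        def rule_doc(r: Rule) -> dict:
            doc = {
                "id": r.id,
                "mode": r.mode,
                "conditions": [{"var": v, "op": o, "threshold": t}
                               for v, o, t in r.conditions],
            }
            if r.text is not None:
                doc["text"] = r.text
            if r.children:
                doc["children"] = [rule_doc(c) for c in r.children]
            return doc

        return {"rules": [rule_doc(r) for r in self.rules]}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_doc(), fh, indent=1)


def _rule_from_doc(doc: dict) -> Rule:
    conds = [(c["var"], c["op"], c["threshold"]) for c in doc.get("conditions", [])]
    children = [_rule_from_doc(c) for c in doc.get("children", [])]
    return Rule(id=doc["id"], conditions=conds, text=doc.get("text"),
                mode=doc.get("mode", "all"), children=children)


def load_rulebase(source) -> RuleBase:
    """Load and validate a rulebase from a JSON file path or a parsed dict."""
    if isinstance(source, dict):
        doc = source
    else:
        with open(source) as fh:
            doc = json.load(fh)
    if "rules" not in doc:
        raise ValueError("rulebase document must contain a 'rules' list")
    return RuleBase([_rule_from_doc(r) for r in doc["rules"]])


def default_rulebase() -> RuleBase:
    """The shipped rulebase: the five published example rules, generalised.

    Layout: a "normal" rule on both phase totals; a placing-over-time branch
    whose sub-rule checks the mean accelerations; a turning-over-time branch
    whose sub-rule checks roll angular velocity; inactivity rules per phase;
    and the per-disc delay family over all 60 discs of each phase.
    """
    rules = [
        Rule(
            id="normal",
            conditions=[("tt_p", "<", "max_t_p"), ("tt_p", ">", "min_t_p"),
                        ("tt_t", "<", "max_t_t"), ("tt_t", ">", "min_t_t")],
            text=NORMAL_TEXT,
        ),
        Rule(
            id="placing_over_time",
            conditions=[("tt_p", ">", "max_t_p")],
            children=[
                Rule(
                    id="placing_low_acceleration",
                    mode="any",
                    conditions=[("acc_x_p", "<", "nacc_x_p"),
                                ("acc_y_p", "<", "nacc_y_p"),
                                ("acc_z_p", "<", "nacc_z_p")],
                    text="Inadequate movement in placing. Possible restriction "
                         "of the elbow and/or shoulder joint.",
                ),
            ],
        ),
        Rule(
            id="turning_over_time",
            conditions=[("tt_t", ">", "max_t_t")],
            children=[
                Rule(
                    id="turning_low_rotation",
                    conditions=[("rot_r_t", "<", "nrot_r_t")],
                    text="Insufficient rotation in turning. "
                         "Possible restriction of pro-sup.",
                ),
            ],
        ),
        Rule(id="thinking_time_placing",
             conditions=[("th_p", ">", "n_th_p")],
             text="High inactive waiting time."),
        Rule(id="thinking_time_turning",
             conditions=[("th_t", ">", "n_th_t")],
             text="High inactive waiting time."),
    ]
    for i in range(1, 61):
        rules.append(Rule(id=f"disc{i}_placing_delay",
                          conditions=[(f"d{i}_p", ">", "n_d_p")],
                          text=f"Delay in placing on disc {i}."))
        rules.append(Rule(id=f"disc{i}_turning_delay",
                          conditions=[(f"d{i}_t", ">", "n_d_t")],
                          text=f"Delay in turning on disc {i}."))
    return RuleBase(rules)


def evaluate_rules(
    ctx: dict,
    thresholds: Thresholds,
    rulebase: RuleBase,
    suppress_normal: bool = True,
) -> list[Finding]:
    """Fire every satisfied rule against a measurement context.

    Findings appear in rule declaration order; sub-rules are evaluated only
    when their parent fires; variables missing from the context never fire.
    With ``suppress_normal`` (default) the "Normal" finding is dropped
    whenever any abnormal finding is present. Pure function of its inputs.
    """
    rulebase.validate_thresholds(thresholds)
    findings: list[Finding] = []

    def visit(rule: Rule) -> None:
        if not rule.fires(ctx, thresholds):
            return
        if rule.text is not None:
            findings.append(Finding(rule.id, rule.text))
        for child in rule.children:
            visit(child)

    for rule in rulebase.rules:
        visit(rule)
    if suppress_normal and any(f.text != NORMAL_TEXT for f in findings):
        findings = [f for f in findings if f.text != NORMAL_TEXT]
    return findings
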