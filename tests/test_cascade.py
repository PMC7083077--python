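"""Filter cascade: boundary semantics, order-invariance, pair oracle."""

import itertools

import numpy as np
import pytest

from exosf.annotations import (
    AssertionRecord,
    AssertionStore,
    FrequencyRecord,
    FrequencyStore,
    VariantAnnotation,
    annotate_variant,
)
from exosf.cascade import (
    FilterConfig,
    assertion_filter,
    consequence_filter,
    frequency_filter,
    genotype_qc_filter,
    panel_filter,
    run_cascade,
)
from exosf.registry import load_default_panel
from exosf.variants import CONSEQUENCE_CLASSES, make_key
from exosf.vcfio import GenotypeCall

CONFIG = FilterConfig()
PANEL = load_default_panel()


def _ann(**kwargs):
    defaults = dict(key=make_key("1", 100, "A", "G"))
    defaults.update(kwargs)
    return VariantAnnotation(**defaults)


# ------------------------------------------------------- variant-level

def test_panel_membership():
    assert panel_filter(_ann(gene="LDLR"), PANEL)
    assert not panel_filter(_ann(gene="TTN"), PANEL)
    assert not panel_filter(_ann(gene=None), PANEL)


@pytest.mark.parametrize("consequence", CONSEQUENCE_CLASSES)
def test_consequence_keep_list(consequence):
    keep = consequence in {
        "stop_gained", "stop_lost", "start_lost", "frameshift",
        "canonical_splice", "near_splice_within_10bp", "inframe_indel", "missense",
    }
    assert consequence_filter(_ann(consequence=consequence)) is keep


def _freq(per_source):
    return FrequencyRecord(key=make_key("1", 100, "A", "G"), per_source=per_source)


@pytest.mark.parametrize(
    "per_source, keep",
    [
        ({"gnomad": 0.02}, False),
        ({"gnomad": 0.01}, False),  # threshold is strict: < 1%
        ({"gnomad": 0.009, "dbsnp": 0.0, "inhouse": 0.005}, True),
        ({}, True),
        ({"custom_source": 0.5}, False),  # open-ended source labels
    ],
)
def test_frequency_threshold(per_source, keep):
    ann = _ann(frequencies=_freq(per_source))
    assert frequency_filter(ann, CONFIG) is keep


def test_frequency_absent_record_keeps():
    assert frequency_filter(_ann(frequencies=None), CONFIG)


@pytest.mark.parametrize(
    "assertion, keep",
    [
        ("pathogenic", True), ("likely_pathogenic", True),
        ("vus", False), ("conflicting", False), ("benign", False),
        ("likely_benign", False), ("absent", False),
    ],
)
def test_assertion_acceptance(assertion, keep):
    assert assertion_filter(_ann(assertion=assertion), CONFIG) is keep


# ------------------------------------------------------- genotype QC

def _call(zyg="het", dp=30, gq=99, ref=None, alt=None, ratio=None):
    if ratio is not None:
        alt = round(dp * ratio)
        ref = dp - alt
    return GenotypeCall("S1", zyg, dp, gq, ref, alt)


@pytest.mark.parametrize(
    "call, keep",
    [
        (_call(dp=14, ratio=0.5), False),   # DP below 15 drops
        (_call(dp=15, ratio=0.5), True),    # DP 15 passes (strict lower bound)
        (_call(gq=19, ratio=0.5), False),   # GQ below 20 drops
        (_call(gq=20, ratio=0.5), True),    # GQ 20 passes
        (GenotypeCall("S1", "het", 100, 99, 71, 29), False),   # ratio 0.29
        (GenotypeCall("S1", "het", 100, 99, 70, 30), True),    # 0.30 inclusive
        (GenotypeCall("S1", "het", 100, 99, 30, 70), True),    # 0.70 inclusive
        (GenotypeCall("S1", "het", 100, 99, 29, 71), False),   # 0.71
        (GenotypeCall("S1", "hom_alt", 100, 99, 15, 85), False),  # 0.85 strict
        (GenotypeCall("S1", "hom_alt", 100, 99, 14, 86), True),   # 0.86 passes
        (GenotypeCall("S1", "hemizygous", 100, 99, 10, 90), True),
        (GenotypeCall("S1", "het", None, 99, 50, 50), False),  # missing DP
        (GenotypeCall("S1", "het", 50, None, 25, 25), False),  # missing GQ
        (GenotypeCall("S1", "het", 50, 99, None, None), False),  # missing AD
        (GenotypeCall("S1", "hom_ref", 50, 99, 50, 0), False),  # not a carrier
    ],
)
def test_genotype_qc_boundaries(call, keep):
    assert genotype_qc_filter(call, CONFIG) is keep


# ------------------------------------------------------- cascade properties

def _random_cohort(rng, n_samples, n_variants):
    """A random in-memory cohort with adversarial annotation mixtures."""
    samples = [f"S{i}" for i in range(n_samples)]
    genes = ["LDLR", "MUTYH", "BRCA1", "TTN", None]
    consequences = ["missense", "frameshift", "synonymous", "intronic_other"]
    assertions = ["pathogenic", "likely_pathogenic", "vus", "benign", "absent"]
    stream, arecs, frecs = [], {}, {}
    for v in range(n_variants):
        key = make_key("1", 1000 + 7 * v, "A", "G")
        gene = genes[int(rng.integers(len(genes)))]
        if gene is not None:
            arecs[key] = AssertionRecord(
                key=key,
                gene=gene,
                consequence=consequences[int(rng.integers(len(consequences)))],
                assertion=assertions[int(rng.integers(len(assertions)))],
            )
        if rng.random() < 0.7:
            frecs[key] = FrequencyRecord(
                key=key,
                per_source={"gnomad": float(rng.choice([0.0, 0.005, 0.02, 0.3]))},
            )
        calls = []
        for s in samples:
            zyg = str(rng.choice(["hom_ref", "het", "hom_alt"], p=[0.5, 0.35, 0.15]))
            dp = int(rng.integers(5, 60))
            alt = {"hom_ref": 0, "het": int(rng.integers(0, dp + 1)),
                   "hom_alt": int(rng.integers(dp - 5, dp + 1))}[zyg]
            alt = max(0, min(alt, dp))
            calls.append(GenotypeCall(s, zyg, dp, int(rng.integers(5, 100)),
                                      dp - alt, alt))
        stream.append((key, calls))
    return stream, AssertionStore(arecs), FrequencyStore(frecs)


def _brute_force(stream, assertions, frequencies, registry, config):
    """Test every (variant, sample) pair against the predicate conjunction."""
    survivors = {}
    for key, calls in stream:
        ann = annotate_variant(key, assertions, frequencies, registry)
        for call in calls:
            ok = (
                call.is_carrier
                and panel_filter(ann, registry)
                and consequence_filter(ann)
                and frequency_filter(ann, config)
                and assertion_filter(ann, config)
                and genotype_qc_filter(call, config)
            )
            if ok:
                survivors.setdefault(key, set()).add(call.sample_id)
    return survivors


def test_cascade_equals_pairwise_oracle_on_small_cohorts():
    rng = np.random.default_rng(20240917)
    for trial in range(30):
        n_samples = int(rng.integers(1, 6))
        n_variants = int(rng.integers(1, 51))
        stream, assertions, frequencies = _random_cohort(rng, n_samples, n_variants)
        expected = _brute_force(stream, assertions, frequencies, PANEL, CONFIG)
        findings, counts = run_cascade(stream, assertions, frequencies, PANEL, CONFIG)
        got = {f.key: {c.sample_id for c in f.carriers} for f in findings}
        assert got == expected, f"trial {trial}"
        assert counts.check_monotone()


def test_variant_level_filters_are_order_insensitive():
    rng = np.random.default_rng(11)
    stream, assertions, frequencies = _random_cohort(rng, 3, 40)
    anns = [annotate_variant(k, assertions, frequencies, PANEL) for k, _ in stream]
    predicates = [
        lambda a: panel_filter(a, PANEL),
        consequence_filter,
        lambda a: frequency_filter(a, CONFIG),
        lambda a: assertion_filter(a, CONFIG),
    ]
    reference = {a.key for a in anns if all(p(a) for p in predicates)}
    for order in itertools.permutations(range(4)):
        surviving = {a.key for a in anns if all(predicates[i](a) for i in order)}
        assert surviving == reference


def test_empty_stream_gives_zero_counts():
    findings, counts = run_cascade(
        [], AssertionStore({}), FrequencyStore({}), PANEL, CONFIG
    )
    assert findings == []
    assert all(v == (0, 0) for v in counts.counts.values())
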