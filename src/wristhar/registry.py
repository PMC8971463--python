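"""Default activity registry: a 40-item battery of child activities.

The battery mixes playful, mostly repetitive movement sequences (high
amplitude, many short bouts per session) with single everyday actions
(lower amplitude, 2-5 repeats each), yielding a strongly imbalanced
bout distribution.  ``pray`` and ``clapping`` form a deliberately
confusable pair: identical spectral shape, different execution speed.
"""

from __future__ import annotations

from wristhar.synthetic import ActivityTemplate

# (name, type); playful entries are the animal-walk style sequences.
_ACTIVITY_TABLE: tuple[tuple[str, str], ...] = (
    ("hopscotch", "playful"),
    ("ball", "everyday"),
    ("goliath", "playful"),
    ("drawing", "playful"),
    ("crab", "playful"),
    ("swimming", "playful"),
    ("spider", "playful"),
    ("seal", "playful"),
    ("building_blocks", "everyday"),
    ("bear", "playful"),
    ("light_off", "everyday"),
    ("dwarf", "playful"),
    ("rabbit", "playful"),
    ("book", "everyday"),
    ("nose", "everyday"),
    ("light_on", "everyday"),
    ("door_handle", "everyday"),
    ("peck", "everyday"),
    ("frog", "playful"),
    ("glass_grabbing", "everyday"),
    ("pudding_eat", "everyday"),
    ("clapping", "everyday"),
    ("drinking", "everyday"),
    ("glass_lifting", "everyday"),
    ("sock_on_same", "everyday"),
    ("sock_on_other", "everyday"),
    ("toothbrush_other", "everyday"),
    ("hand_wash", "everyday"),
    ("snack_eat", "everyday"),
    ("knee_same", "everyday"),
    ("knee_other", "everyday"),
    ("shoe_on_same", "everyday"),
    ("pray", "everyday"),
    ("toothbrush_same", "everyday"),
    ("glass_to_mouth", "everyday"),
    ("shoe_off_other", "everyday"),
    ("shoe_on_other", "everyday"),
    ("sock_off_same", "everyday"),
    ("sock_off_other", "everyday"),
    ("shoe_off_same", "everyday"),
)

# The confusable pair shares one spectral template and differs in speed.
_PRAY_CLAP_BASE_HZ = 1.4
_CLAP_TEMPO_RATIO = 1.25


def default_registry() -> tuple[ActivityTemplate, ...]:
    """Build the packaged 40-activity registry.

    Frequency signatures are spread deterministically over 0.6-6 Hz so
    most activities are separable at the generator's default subject
    variability; amplitudes and repeat ranges differ by activity type to
    reproduce tens-vs-hundreds bout imbalance at cohort scale.
    """
    templates: list[ActivityTemplate] = []
    playful_idx = 0
    everyday_idx = 0
    for name, kind in _ACTIVITY_TABLE:
        if name == "pray":
            templates.append(_pray_template())
            continue
        if name == "clapping":
            templates.append(_pray_template().with_tempo(_CLAP_TEMPO_RATIO, "clapping"))
            continue
        if kind == "playful":
            # repetitive gross-motor sequences: 1.5-6 Hz, strong on both groups
            f = 1.5 + 0.45 * playful_idx
            playful_idx += 1
            templates.append(
                ActivityTemplate(
                    name=name,
                    activity_type=kind,
                    base_frequencies=((f, 2.0 * f), (f,)),
                    amplitudes=(1.2, 0.9),
                    bout_duration=(1.2, 0.3),
                    repeats_per_subject=(8, 40) if name != "hopscotch" else (20, 80),
                    noise_sd=0.08,
                )
            )
        else:
            # single everyday actions: 0.6-4 Hz, weaker gyroscope content
            f = 0.6 + 0.12 * everyday_idx
            everyday_idx += 1
            templates.append(
                ActivityTemplate(
                    name=name,
                    activity_type=kind,
                    base_frequencies=((f,), (1.7 * f,)),
                    amplitudes=(0.5, 0.25),
                    bout_duration=(2.0, 0.5),
                    repeats_per_subject=(2, 5),
                    noise_sd=0.06,
                )
            )
    return tuple(templates)


def _pray_template() -> ActivityTemplate:
    return ActivityTemplate(
        name="pray",
        activity_type="everyday",
        base_frequencies=((_PRAY_CLAP_BASE_HZ,), (1.7 * _PRAY_CLAP_BASE_HZ,)),
        amplitudes=(0.5, 0.25),
        bout_duration=(2.0, 0.5),
        repeats_per_subject=(2, 5),
        noise_sd=0.06,
    )


def confusable_pair(
    name_a: str,
    name_b: str,
    base_frequency: float = 1.4,
    tempo_ratio: float = 1.2,
    activity_type: str = "everyday",
) -> tuple[ActivityTemplate, ActivityTemplate]:
    """Two templates sharing a spectral shape, differing only in speed."""
    a = ActivityTemplate(
        name=name_a,
        activity_type=activity_type,
        base_frequencies=((base_frequency,), (1.7 * base_frequency,)),
        amplitudes=(0.5, 0.25),
        bout_duration=(2.0, 0.5),
        repeats_per_subject=(3, 6),
        noise_sd=0.06,
    )
    return a, a.with_tempo(tempo_ratio, name_b)
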