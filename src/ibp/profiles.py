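"""Built-in profile definitions.

Two profiles ship with the package, matching the two published variants of
the individual-behavioral-profiling procedure in the juvenile-stress +
underwater-trauma rat model:

``IBP1`` — seven parameters from the water-associated zero maze (WAZM) and
elevated plus maze (EPM), identical at the post-trauma and post-treatment
time points.

``IBP2`` — seven parameters per time point sharing five (WAZM closed-arm
distance, open-arm time, open-arm distance, total freezing; social
recognition preference index).  At post-trauma the remaining two come from
the open field test (total distance, center time); at post-treatment they
are replaced by EPM total distance and EPM anxiety index, because control
animals no longer explore a familiar open field.

Pathological directions are not stated parameter-by-parameter in the source
procedure ("either lower or higher than the cut-off"); the shipped
directions follow the tail the affected groups occupy in the published group
contrasts: exploration measures (distances, open-arm/center times, social
preference) are low_is_affected, while freezing, closed-arm time and the
anxiety index are high_is_affected.  Custom profiles may override any
direction.
"""

from __future__ import annotations

from .cohort import Direction, ParameterSpec, ProfileDefinition, POST_TRAUMA, POST_TREATMENT
from .exceptions import ProfileLookupError

LOW = Direction.LOW_IS_AFFECTED
HIGH = Direction.HIGH_IS_AFFECTED

_IBP1_PARAMS = (
    ParameterSpec("wazm_total_distance", "WAZM", LOW, "cm"),
    ParameterSpec("wazm_closed_arms_time", "WAZM", HIGH, "s"),
    ParameterSpec("wazm_closed_arms_distance", "WAZM", LOW, "cm"),
    ParameterSpec("wazm_open_arms_distance", "WAZM", LOW, "cm"),
    ParameterSpec("wazm_total_freezing", "WAZM", HIGH, "s"),
    ParameterSpec("epm_total_freezing", "EPM", HIGH, "s"),
    ParameterSpec("epm_anxiety_index", "EPM", HIGH, "%"),
)

# Five parameters shared by both IBP2 time points.
_IBP2_SHARED = (
    ParameterSpec("wazm_closed_arms_distance", "WAZM", LOW, "cm"),
    ParameterSpec("wazm_open_arms_time", "WAZM", LOW, "s"),
    ParameterSpec("wazm_open_arms_distance", "WAZM", LOW, "cm"),
    ParameterSpec("wazm_total_freezing", "WAZM", HIGH, "s"),
    ParameterSpec("srt_preference_index", "SRT", LOW, "index"),
)

_IBP2_POST_TRAUMA = _IBP2_SHARED + (
    ParameterSpec("oft_total_distance", "OFT", LOW, "cm"),
    ParameterSpec("oft_center_time", "OFT", LOW, "s"),
)

_IBP2_POST_TREATMENT = _IBP2_SHARED + (
    ParameterSpec("epm_total_distance", "EPM", LOW, "cm"),
    ParameterSpec("epm_anxiety_index", "EPM", HIGH, "%"),
)

_BUILTINS = {
    "IBP1": ProfileDefinition(
        "IBP1",
        {POST_TRAUMA: _IBP1_PARAMS, POST_TREATMENT: _IBP1_PARAMS},
        k=4,
    ),
    "IBP2": ProfileDefinition(
        "IBP2",
        {POST_TRAUMA: _IBP2_POST_TRAUMA, POST_TREATMENT: _IBP2_POST_TREATMENT},
        k=4,
    ),
}


def builtin_profile(profile_id: str) -> ProfileDefinition:
    """Return a shipped profile definition by id.

    Pure: repeated calls return equal (identical) definitions.

    Raises
    ------
    ProfileLookupError
        For an unknown id; the message lists the valid ids.
    """
    try:
        return _BUILTINS[profile_id]
    except KeyError:
        raise ProfileLookupError(
            f"unknown profile id {profile_id!r}; valid ids: {sorted(_BUILTINS)}"
        ) from None
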