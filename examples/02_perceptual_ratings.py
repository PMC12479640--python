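"""Rate, reach consensus and classify swallow coordination.

Builds two raters' perceptual profiles for one neonate, resolves their one
disagreement, and classifies the consensus profile with the rule-based
coordinated/uncoordinated classifier.
"""

from swallowsound.perceptual import (
    BREATH_SOUNDS,
    PerceptualProfile,
    Phase,
    Rating,
    RatingValue,
    classify_coordination,
    consensus,
    presence_from_swallows,
)

YES, NO = Rating(RatingValue.YES), Rating(RatingValue.NO)


def profile(rater, wheeze_post):
    ratings = {}
    for name in BREATH_SOUNDS:
        ratings[(Phase.PRE, name)] = YES if name == "normal_breathing" else NO
        ratings[(Phase.POST, name)] = YES if name == "normal_breathing" else NO
    ratings[(Phase.POST, "wheeze")] = wheeze_post
    ratings[(Phase.DURING, "bolus_transit_sound")] = YES
    ratings[(Phase.DURING, "glottal_release_sound")] = NO
    return PerceptualProfile("neonate_01", rater, ratings)


rater_a = profile("rater_a", wheeze_post=YES)
rater_b = profile("rater_b", wheeze_post=NO)

merged = consensus(rater_a, rater_b,
                   resolutions={(Phase.POST, "wheeze"): NO})
print(f"consensus post-swallow wheeze: "
      f"{merged.get(Phase.POST, 'wheeze').value.value}")
print(f"coordination class           : {classify_coordination(merged).value}")

# file-level presence: a sound heard on 5 of 6 swallows is consistent
# (> 80% of swallows), on 4 of 5 it is not (the 80% boundary is excluded)
for vec in ([True] * 5 + [False], [True] * 4 + [False]):
    r = presence_from_swallows(vec)
    print(f"present on {sum(vec)}/{len(vec)} swallows -> value={r.value.value},"
          f" consistent={r.consistent}")
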