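"""Train a prototype network on a handful of pocket scenes and classify one.

Renders a few labelled scenes, turns each into a 256-byte feature vector
(ROI crop + 16x16 box-average downscale), trains the network until stable,
then classifies an unseen boat-position olive.  The printed recognition
shows the winner-takes-all outcome: which neurons fired, at what L1
distance, and the decided category.
"""

from olivesort import (
    DEFAULT_ROI, NetworkProfile, RceNetwork, ResolutionProfile,
    SceneSpec, crop_roi, render_scene, to_feature_vector,
)

res = ResolutionProfile(16, 16, "cm1k")


def vec(case, angle, seed):
    img, _ = render_scene(SceneSpec(case=case, angle=angle, seed=seed))
    return to_feature_vector(crop_roi(img, DEFAULT_ROI), res)


net = RceNetwork(NetworkProfile.builtin("cm1k"))
train = [("normal", 0.0), ("normal", 6.0), ("boat", 85.0), ("boat", -88.0),
         ("empty", 0.0), ("empty", 0.0)]
vectors = [vec("olive" if c != "empty" else "empty", a, seed=i)
           for i, (c, a) in enumerate(train)]
net.fit(vectors, [c for c, _ in train])
print(f"committed neurons: {len(net)} (categories {net.categories})")

probe = vec("olive", -83.0, seed=99)  # unseen boat-position olive
rec = net.classify_rbf(probe)
print(f"recognition: {rec.status}, category={rec.category}, "
      f"L1 distance={rec.distance}")
print(f"firing neurons (commit_index, category, distance): {rec.firing}")
print(f"nearest 3 prototypes ignoring fields: "
      f"{net.classify_knn(probe, 3).neighbors}")
# The winner is "boat" (nearest firing neuron).  With only six training
# examples the influence fields stay wide, so distant normal neurons also
# fire and the status is "uncertain" rather than "identified" -- more
# training shrinks wrong-category fields and sharpens the outcome.
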