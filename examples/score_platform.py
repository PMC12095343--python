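"""Platform scoring: content push ranking and user satisfaction.

Scores three content items against a push strategy over two user groups,
then computes a weighted satisfaction score from service-quality ratings.
"""

import numpy as np

from sparrowalloc import rank_contents, satisfaction_score

# rows = content items, columns = user-group affinities
affinity = np.array(
    [
        [0.9, 0.1],  # hygiene basics: mostly group 1
        [0.2, 0.8],  # outbreak response: mostly group 2
        [0.5, 0.5],  # vaccination info: both
    ]
)
strategy = np.array([0.7, 0.3])  # current push strategy favors group 1

scores, order = rank_contents(affinity, strategy)
names = ["hygiene basics", "outbreak response", "vaccination info"]
print("push scores:", {n: round(float(s), 3) for n, s in zip(names, scores)})
print("push order :", [names[i] for i in order])

quality = np.array([8.0, 6.0, 9.0, 7.0])  # per-service quality ratings
weights = np.array([0.4, 0.2, 0.3, 0.1])  # importance weights (sum to 1)
print(f"satisfaction score: {satisfaction_score(quality, weights):.2f} / 10")
# The satisfaction score is a convex combination, so it always lies between
# the worst and best service rating.
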