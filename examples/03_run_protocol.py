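"""Run the train/test protocol on a synthetic feed (scaled-down sizing).

Trains a fresh 256-byte-profile network on up to 100 examples per class of
the three-way scheme (normal / boat / empty), then runs 5 repetitions of
100 random test draws per class.  The report mirrors the field protocol:
one error rate per repetition, their mean as the total, and the committed
neuron count.  At full sizing the protocol uses 300 per class and 10
repetitions (3000 presentations per case).
"""

from olivesort import ProtocolConfig, run_protocol
from olivesort.evaluate import report
from olivesort.labeler import scheme_classes
from olivesort.synthetic import generate_dataset

dataset = generate_dataset({c: 200 for c in scheme_classes("simple")},
                           scheme="simple", seed=11)
cfg = ProtocolConfig(scheme="simple", network="cm1k", resolution=(16, 16),
                     train_cap=100, reps=5, test_per_case=100, seed=11)
result = run_protocol(dataset, cfg)
text, data = report(result)
print(text)
print("last repetition confusion matrix (rows=truth):")
print(result.confusions[-1])
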