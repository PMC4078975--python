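# Demo run on synthetic data at desk scale: two tasks, coronal-only and
# combined coronal+sagittal features, the 30-repetition AUC protocol, and
# stability-selection ranking with traceback on the neuron-vs-oligodendrocyte
# task. The [synthetic] section is omitted, so the generator defaults apply
# (5 genes per enriched class, 10 negatives, 128-px images, noise-free).

out_dir = "demo_out"
words_single = 64
words_combined = 32
tasks = [["N-vs-Neg", 1.5], ["N-vs-O", 1.5]]
sections = ["coronal", "combined"]
n_reps = 30
seed = 0

[ranking]
task = "N-vs-O"
threshold = 1.5
section = "coronal"
subsamples = 100
top = 10
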