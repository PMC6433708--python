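phrase	doc_freq
transcranial magnetic stimulation	495
electrical stimulation	296
induced movement therapy	251
robot therapy	125
mental practice	97
mirror therapy	97
intensive occupational therapy	95
motor training	74
somatosensory stimulation	60
repetitive practice	48
intensive training	44
neuromuscular electrical stimulation	40
bilateral training	32
bilateral arm training	29
noninvasive brain stimulation	27
cortical stimulation	24
tactile stimulation	24
upper extremity training	24
hand training	23
neuromuscular stimulation	22
median nerve stimulation	20
task practice therapy	19
aerobic exercise training	17
unilateral training	17
treadmill training	15
peripheral nerve stimulation	14
bimanual training	13
gait training	13
motor imagery training	13
computer interface training	12
smart arm training	12
massed practice	10
transcutaneous electrical nerve stimulation	10
virtual reality training	10
physical and occupational therapy	9
active neuromuscular stimulation	8
deep brain stimulation	7
functional strength training	7
functional task practice	7
motor cortex stimulation	7
music therapy	7
wrist training	7
based mental practice training	6
constraint-induced movement therapy	6
forced use therapy	6
paired associative stimulation	6
surface neuromuscular electrical stimulation	6
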