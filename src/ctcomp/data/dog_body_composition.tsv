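# Reference whole-body CT composition of 12 dogs (6 beagles, 6 greyhounds)
# on study days 0 and 28 of a weight-gain protocol; tissue masses in kg.
id	breed	day	bone_kg	lean_kg	fat_kg
beagle_1	beagle	0	1.7	6.0	3.9
beagle_1	beagle	28	1.7	6.7	4.8
beagle_2	beagle	0	1.8	6.4	2.5
beagle_2	beagle	28	1.8	7.4	3.4
beagle_3	beagle	0	1.6	5.6	2.7
beagle_3	beagle	28	1.6	6.2	3.3
beagle_4	beagle	0	1.7	7.3	2.8
beagle_4	beagle	28	1.7	7.9	3.1
beagle_5	beagle	0	1.4	5.8	3.2
beagle_5	beagle	28	1.4	6.1	3.9
beagle_6	beagle	0	1.5	6.1	2.3
beagle_6	beagle	28	1.5	6.6	2.9
greyhound_1	greyhound	0	3.5	19.7	3.5
greyhound_1	greyhound	28	3.5	20.3	4.0
greyhound_2	greyhound	0	3.2	17.4	1.7
greyhound_2	greyhound	28	3.2	18.3	2.6
greyhound_3	greyhound	0	3.4	20.2	2.6
greyhound_3	greyhound	28	3.4	21.0	3.9
greyhound_4	greyhound	0	3.4	19.5	3.5
greyhound_4	greyhound	28	3.4	20.3	4.0
greyhound_5	greyhound	0	3.0	17.1	2.6
greyhound_5	greyhound	28	3.0	17.7	3.2
greyhound_6	greyhound	0	3.3	19.0	2.0
greyhound_6	greyhound	28	3.3	20.0	3.5
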