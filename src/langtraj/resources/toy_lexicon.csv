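category,term,weight
fp_singular,i,1
fp_singular,me,1
fp_singular,my,1
fp_singular,mine,1
fp_singular,myself,1
fp_singular,i'm,1
fp_singular,i've,1
fp_singular,i'd,1
fp_plural,we,1
fp_plural,us,1
fp_plural,our,1
fp_plural,ours,1
fp_plural,ourselves,1
fp_plural,we're,1
fp_plural,we've,1
articles,a,1
articles,an,1
articles,the,1
social,friend*,1
social,help*,1
social,talk*,1
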