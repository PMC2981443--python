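element,intercept,exponent,source
humerus,0.6821439404091358,-0.3204968826792601,least-squares fit to printed humerus (mass; expectation) pairs
femur,0.9306875038585173,-0.3204968826792601,humerus slope anchored through the single printed femur pair
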