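raw_label	static_class
hands and knees	Hands and Knees
crawling	Hands and Knees
pivoting	Prone
prone	Prone
side lying	Prone
belly crawling	Prone
supported sitting by the caregiver	Sitting
supported sitting using own hands as support	Sitting
independent sitting	Sitting
supine	Supine
supported stand	Upright
standing upright	Upright
walking	Upright
supported walking	Upright
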