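<svg xmlns="http://www.w3.org/2000/svg" width="500" height="500" viewBox="0 0 500 500">
<rect width="500" height="500" fill="white"/>
<path d="M 250.000 25.000 A 225.000 225.000 0 0 1 444.856 362.500 L 410.215 342.500 A 185.000 185.000 0 0 0 250.000 65.000 Z" fill="#c6dbef" stroke="none"/>
<path d="M 444.856 362.500 A 225.000 225.000 0 0 1 362.500 444.856 L 342.500 410.215 A 185.000 185.000 0 0 0 410.215 342.500 Z" fill="#08306b" stroke="none"/>
<path d="M 362.500 444.856 A 225.000 225.000 0 0 1 55.144 362.500 L 89.785 342.500 A 185.000 185.000 0 0 0 342.500 410.215 Z" fill="#c6dbef" stroke="none"/>
<path d="M 55.144 362.500 A 225.000 225.000 0 0 1 28.418 210.929 L 67.811 217.875 A 185.000 185.000 0 0 0 89.785 342.500 Z" fill="#4292c6" stroke="none"/>
<path d="M 28.418 210.929 A 225.000 225.000 0 0 1 250.000 25.000 L 250.000 65.000 A 185.000 185.000 0 0 0 67.811 217.875 Z" fill="#c6dbef" stroke="none"/>
<path d="M 250.000 72.000 A 178.000 178.000 0 0 1 404.153 339.000 L 375.574 322.500 A 145.000 145.000 0 0 0 250.000 105.000 Z" fill="#a6d96a" stroke="none"/>
<path d="M 404.153 339.000 A 178.000 178.000 0 0 1 339.000 404.153 L 322.500 375.574 A 145.000 145.000 0 0 0 375.574 322.500 Z" fill="#08306b" stroke="none"/>
<path d="M 339.000 404.153 A 178.000 178.000 0 0 1 95.847 339.000 L 124.426 322.500 A 145.000 145.000 0 0 0 322.500 375.574 Z" fill="#a50026" stroke="none"/>
<path d="M 95.847 339.000 A 178.000 178.000 0 0 1 74.704 219.091 L 107.203 224.821 A 145.000 145.000 0 0 0 124.426 322.500 Z" fill="#4292c6" stroke="none"/>
<path d="M 74.704 219.091 A 178.000 178.000 0 0 1 250.000 72.000 L 250.000 105.000 A 145.000 145.000 0 0 0 107.203 224.821 Z" fill="#a6d96a" stroke="none"/>
<path d="M 250.000 112.000 A 138.000 138.000 0 0 1 369.512 319.000 L 340.933 302.500 A 105.000 105.000 0 0 0 250.000 145.000 Z" fill="#a6d96a" stroke="none"/>
<path d="M 369.512 319.000 A 138.000 138.000 0 0 1 319.000 369.512 L 302.500 340.933 A 105.000 105.000 0 0 0 340.933 302.500 Z" fill="#08306b" stroke="none"/>
<path d="M 319.000 369.512 A 138.000 138.000 0 0 1 130.488 319.000 L 159.067 302.500 A 105.000 105.000 0 0 0 302.500 340.933 Z" fill="#1a9850" stroke="none"/>
<path d="M 130.488 319.000 A 138.000 138.000 0 0 1 114.097 226.037 L 146.595 231.767 A 105.000 105.000 0 0 0 159.067 302.500 Z" fill="#4292c6" stroke="none"/>
<path d="M 114.097 226.037 A 138.000 138.000 0 0 1 250.000 112.000 L 250.000 145.000 A 105.000 105.000 0 0 0 146.595 231.767 Z" fill="#a6d96a" stroke="none"/>
<path d="M 250.000 152.000 A 98.000 98.000 0 0 1 334.870 299.000 L 306.292 282.500 A 65.000 65.000 0 0 0 250.000 185.000 Z" fill="#a6d96a" stroke="none"/>
<path d="M 334.870 299.000 A 98.000 98.000 0 0 1 299.000 334.870 L 282.500 306.292 A 65.000 65.000 0 0 0 306.292 282.500 Z" fill="#08306b" stroke="none"/>
<path d="M 299.000 334.870 A 98.000 98.000 0 0 1 165.130 299.000 L 193.708 282.500 A 65.000 65.000 0 0 0 282.500 306.292 Z" fill="#f46d43" stroke="none"/>
<path d="M 165.130 299.000 A 98.000 98.000 0 0 1 153.489 232.982 L 185.987 238.713 A 65.000 65.000 0 0 0 193.708 282.500 Z" fill="#4292c6" stroke="none"/>
<path d="M 153.489 232.982 A 98.000 98.000 0 0 1 250.000 152.000 L 250.000 185.000 A 65.000 65.000 0 0 0 185.987 238.713 Z" fill="#006837" stroke="none"/>
<path d="M 250.000 192.000 A 58.000 58.000 0 0 1 300.229 279.000 L 271.651 262.500 A 25.000 25.000 0 0 0 250.000 225.000 Z" fill="#a6d96a" stroke="none"/>
<path d="M 300.229 279.000 A 58.000 58.000 0 0 1 279.000 300.229 L 262.500 271.651 A 25.000 25.000 0 0 0 271.651 262.500 Z" fill="#08306b" stroke="none"/>
<path d="M 279.000 300.229 A 58.000 58.000 0 0 1 199.771 279.000 L 228.349 262.500 A 25.000 25.000 0 0 0 262.500 271.651 Z" fill="#a6d96a" stroke="none"/>
<path d="M 199.771 279.000 A 58.000 58.000 0 0 1 192.881 239.928 L 225.380 245.659 A 25.000 25.000 0 0 0 228.349 262.500 Z" fill="#4292c6" stroke="none"/>
<path d="M 192.881 239.928 A 58.000 58.000 0 0 1 250.000 192.000 L 250.000 225.000 A 25.000 25.000 0 0 0 225.380 245.659 Z" fill="#f46d43" stroke="none"/>
<line x1="250.000" y1="225.000" x2="250.000" y2="25.000" stroke="black" stroke-width="1.5"/>
<line x1="271.651" y1="262.500" x2="444.856" y2="362.500" stroke="black" stroke-width="1.5"/>
<line x1="262.500" y1="271.651" x2="362.500" y2="444.856" stroke="black" stroke-width="1.5"/>
<line x1="228.349" y1="262.500" x2="55.144" y2="362.500" stroke="black" stroke-width="1.5"/>
<line x1="225.380" y1="245.659" x2="28.418" y2="210.929" stroke="black" stroke-width="1.5"/>
</svg>
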